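"""Tree handling shared by the phylogenetic and functional facets.

A "weighted tree" is any rooted dendropy tree with non-negative branch lengths
whose tip labels are species identifiers: the phylogeny and the functional
dendrogram are handled identically. For branch-based beta-diversity the tree
is reduced to arrays: a branch-length vector and a boolean tips x branches
descendancy mask (branch j is ancestral to tip i). The root node itself
carries no branch; root-adjacent branches of a pruned tree are included.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np


class TreeError(ValueError):
    pass


def read_newick(path) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    _check(tree)
    return tree


def tree_from_string(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    _check(tree)
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def _check(tree: dendropy.Tree) -> None:
    labels = tip_labels(tree)
    if len(set(labels)) != len(labels):
        raise TreeError("duplicate tip labels")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise TreeError("negative branch length")


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def prune_to(tree: dendropy.Tree, labels) -> dendropy.Tree:
    """Subtree spanning ``labels``: non-pool tips removed, unifurcations
    collapsed with branch lengths summed, rooted at the pool's MRCA."""
    labels = list(labels)
    have = set(tip_labels(tree))
    missing = sorted(set(labels) - have)
    if missing:
        raise TreeError(f"species absent from tree tips: {missing[:5]}")
    sub = tree.extract_tree_with_taxa_labels(labels)
    sub.seed_node.edge.length = None  # root carries no branch
    # collapse a unifurcating root left by extraction
    while len(sub.seed_node.child_nodes()) == 1 and not sub.seed_node.is_leaf():
        child = sub.seed_node.child_nodes()[0]
        child.edge.length = None
        sub.seed_node = child
        child.parent_node = None
    return sub


def star_tree(labels, length: float = 1.0) -> dendropy.Tree:
    newick = "(" + ",".join(f"{lab}:{length}" for lab in labels) + ");"
    return tree_from_string(newick)


@dataclass
class TreeArrays:
    """Array form of a rooted weighted tree (root edge excluded)."""

    tip_labels: list[str]
    branch_lengths: np.ndarray  # (n_branches,)
    tip_branch_mask: np.ndarray  # bool (n_tips, n_branches)

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths.sum())


def tree_arrays(tree: dendropy.Tree) -> TreeArrays:
    """Flatten a tree into branch lengths and a tip-descendancy mask.

    Every edge except the root's own contributes one branch; a branch is
    "carried" by a tip iff the tip descends from it, so a site contains a
    branch iff at least one descendant tip occurs there.
    """
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    leaf_pos = {id(lf): i for i, lf in enumerate(leaves)}

    lengths: list[float] = []
    masks: list[np.ndarray] = []
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            m = np.zeros(len(leaves), dtype=bool)
            m[leaf_pos[id(node)]] = True
        else:
            m = np.zeros(len(leaves), dtype=bool)
            for ch in node.child_nodes():
                m |= below[id(ch)]
        below[id(node)] = m
        if node is not tree.seed_node:
            lengths.append(float(node.edge.length or 0.0))
            masks.append(m)
    if not masks:  # single-tip tree
        return TreeArrays(labels, np.zeros(0), np.zeros((len(leaves), 0), dtype=bool))
    return TreeArrays(
        tip_labels=labels,
        branch_lengths=np.asarray(lengths, dtype=float),
        tip_branch_mask=np.column_stack(masks),
    )


def root_to_tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    depths: dict[int, float] = {id(tree.seed_node): 0.0}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depths[id(node)] = depths[id(node.parent_node)] + float(node.edge.length or 0.0)
        if node.is_leaf():
            out[node.taxon.label] = depths[id(node)]
    if tree.seed_node.is_leaf():
        out[tree.seed_node.taxon.label] = 0.0
    return out


def phylo_vcv(tree: dendropy.Tree, order: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance matrix: C[i, j] = shared root-to-MRCA path.

    Returns (C, labels) with labels in ``order`` if given.
    """
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    pos = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))

    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    below: dict[int, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            depth[id(node)] = depth[id(node.parent_node)] + float(node.edge.length or 0.0)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            idx = np.array([pos[node.taxon.label]])
        else:
            kids = [below[id(ch)] for ch in node.child_nodes()]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    C[np.ix_(kids[a], kids[b])] = depth[id(node)]
                    C[np.ix_(kids[b], kids[a])] = depth[id(node)]
            idx = np.concatenate(kids)
        below[id(node)] = idx
    for lab, i in pos.items():
        C[i, i] = depth.get(id(leaves[i]), 0.0)
    diag = np.array([depth[id(lf)] for lf in leaves])
    C[np.diag_indices(n)] = diag

    if order is not None:
        missing = sorted(set(order) - set(labels))
        if missing:
            raise TreeError(f"tips missing from tree: {missing[:5]}")
        sel = [pos[lab] for lab in order]
        return C[np.ix_(sel, sel)], list(order)
    return C, labels


def relabel_tips(tree: dendropy.Tree, mapping: dict[str, str]) -> dendropy.Tree:
    """Copy of the tree with tip labels replaced per ``mapping`` (labels not in
    the mapping are kept). Topology and branch lengths untouched."""
    clone = tree.clone(depth=1)
    # deep-clone taxa so the source tree's namespace is untouched
    clone.taxon_namespace = dendropy.TaxonNamespace()
    for lf in clone.leaf_node_iter():
        old = lf.taxon.label
        lf.taxon = clone.taxon_namespace.new_taxon(mapping.get(old, old))
    return clone
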