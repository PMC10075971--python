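"""Multiple-site Sorensen dissimilarity and its turnover/nestedness partition.

The same machinery serves three facets through a unified incidence-of-weighted-
units abstraction: units are species (weight 1, taxonomic facet) or branches of
a pool-pruned tree (weight = branch length; phylogenetic facet on the
phylogeny, functional facet on the trait dendrogram).

With site totals S_i (richness or summed branch length), pool total S_T, and
pairwise exclusive amounts b_ij (units at site i absent from site j):

    a_M     = sum_i S_i - S_T                        (multi-site shared part)
    beta_SIM = sum_min / (sum_min + a_M)             (turnover, Simpson-based)
    beta_SOR = (sum_min + sum_max) / (2 a_M + sum_min + sum_max)
    beta_SNE = beta_SOR - beta_SIM                   (nestedness-resultant)

where sum_min = sum_{i<j} min(b_ij, b_ji) and sum_max the analogue with max.
For two sites these reduce to the classical pairwise Simpson and Sorensen
indices; the decomposition is additive by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grids import CompositionGrid
from .trees import TreeArrays, prune_to, root_to_tip_depths, tree_arrays

FACETS = ("taxonomic", "phylogenetic", "functional")


class PartitionError(ValueError):
    pass


@dataclass
class MultiSiteComponents:
    site_totals: np.ndarray  # S_i per site (richness or branch length)
    pool_total: float  # S_T
    a_m: float  # sum(S_i) - S_T
    sum_min: float  # sum over pairs of min(b_ij, b_ji)
    sum_max: float  # sum over pairs of max(b_ij, b_ji)


@dataclass
class BetaPartition:
    facet: str
    beta_sor: float
    beta_sim: float
    beta_sne: float
    n_sites: int


@dataclass
class BranchIncidence:
    """Sites x branches incidence with branch-length weights."""

    branch_lengths: np.ndarray
    incidence: np.ndarray  # bool, sites x branches


def multisite_components(incidence, unit_weights=None) -> MultiSiteComponents:
    """Components of the multi-site partition for a sites x units matrix.

    ``unit_weights`` defaults to all ones (taxonomic case). Every site must
    contain a positive weighted total.
    """
    inc = np.asarray(incidence)
    if inc.ndim != 2 or inc.shape[0] < 2:
        raise PartitionError("need a 2-D matrix with at least 2 sites")
    inc = inc.astype(bool)
    n_sites, n_units = inc.shape
    w = np.ones(n_units) if unit_weights is None else np.asarray(unit_weights, float)
    if w.shape != (n_units,) or (w < 0).any():
        raise PartitionError("unit_weights must be non-negative, one per unit")

    S = inc @ w
    if not (S > 0).all():
        raise PartitionError("empty site in window")
    shared = (inc * w) @ inc.T
    b = S[:, None] - shared  # b[i, j] = amount exclusive to i w.r.t. j
    iu = np.triu_indices(n_sites, k=1)
    sum_min = float(np.minimum(b, b.T)[iu].sum())
    sum_max = float(np.maximum(b, b.T)[iu].sum())
    pool_total = float(w[inc.any(axis=0)].sum())
    a_m = float(S.sum() - pool_total)
    return MultiSiteComponents(S, pool_total, max(a_m, 0.0), sum_min, sum_max)


def partition_from_components(
    c: MultiSiteComponents, facet: str = "taxonomic"
) -> BetaPartition:
    if facet not in FACETS:
        raise PartitionError(f"unknown facet {facet!r}")
    denom_sim = c.sum_min + c.a_m
    if denom_sim <= 0:
        raise PartitionError("no units anywhere (sum_min + a_M = 0)")
    beta_sim = c.sum_min / denom_sim
    beta_sor = (c.sum_min + c.sum_max) / (2 * c.a_m + c.sum_min + c.sum_max)
    return BetaPartition(
        facet=facet,
        beta_sor=beta_sor,
        beta_sim=beta_sim,
        beta_sne=beta_sor - beta_sim,
        n_sites=len(c.site_totals),
    )


def partition(incidence, unit_weights=None, facet: str = "taxonomic") -> BetaPartition:
    """Convenience: components then partition in one call."""
    return partition_from_components(multisite_components(incidence, unit_weights), facet)


def nestedness_proportion(p: BetaPartition) -> float:
    """beta_SNE / beta_SOR; NaN (flagged missing) when total beta is zero."""
    if p.beta_sor <= 0:
        return math.nan
    return p.beta_sne / p.beta_sor


def partition_subsets(incidence, unit_weights, subsets) -> dict[str, np.ndarray]:
    """Vectorised partitions for many site subsets of one incidence matrix.

    ``subsets`` is an (R, m) integer array of row indices; returns arrays of
    length R for beta_sor / beta_sim / beta_sne. This is the hot path of the
    moving-window engine: the pairwise shared-weight matrix is computed once
    and gathered per subset.
    """
    inc = np.asarray(incidence).astype(bool)
    n_units = inc.shape[1]
    w = np.ones(n_units) if unit_weights is None else np.asarray(unit_weights, float)
    subs = np.asarray(subsets, dtype=np.intp)
    if subs.ndim != 2 or subs.shape[1] < 2:
        raise PartitionError("subsets must be (R, m) with m >= 2")

    S = inc @ w
    if not (S[np.unique(subs)] > 0).all():
        raise PartitionError("empty site in window")
    shared = (inc * w) @ inc.T

    S_sub = S[subs]  # (R, m)
    sh = shared[subs[:, :, None], subs[:, None, :]]  # (R, m, m)
    b = S_sub[:, :, None] - sh
    bt = np.swapaxes(b, 1, 2)
    iu = np.triu_indices(subs.shape[1], k=1)
    sum_min = np.minimum(b, bt)[:, iu[0], iu[1]].sum(axis=1)
    sum_max = np.maximum(b, bt)[:, iu[0], iu[1]].sum(axis=1)
    union = inc[subs].any(axis=1) @ w  # (R,)
    a_m = np.maximum(S_sub.sum(axis=1) - union, 0.0)

    beta_sim = sum_min / (sum_min + a_m)
    beta_sor = (sum_min + sum_max) / (2 * a_m + sum_min + sum_max)
    return {
        "beta_sor": beta_sor,
        "beta_sim": beta_sim,
        "beta_sne": beta_sor - beta_sim,
    }


def branch_incidence(tree, comp: CompositionGrid, pool) -> BranchIncidence:
    """Sites x branches incidence on the pool-pruned tree.

    ``pool`` is the regional species pool (must cover every species present in
    ``comp``); a branch is present at a site iff at least one descendant tip
    occurs there. A single-species pool degenerates to one branch whose length
    is that tip's root-to-tip path in the source tree.
    """
    pool = sorted(pool)
    extra = sorted(set(comp.species) - set(pool))
    if extra:
        raise PartitionError(f"species present but outside pool: {extra[:5]}")
    if len(pool) == 1:
        depth = root_to_tip_depths(tree).get(pool[0])
        if depth is None:
            raise PartitionError(f"species absent from tree tips: {pool}")
        inc = comp.incidence[:, [comp.species.index(pool[0])]].astype(bool)
        return BranchIncidence(np.array([depth]), inc)
    pruned = prune_to(tree, pool)
    arr = tree_arrays(pruned)
    return branch_incidence_from_arrays(arr, comp.incidence.astype(bool), comp.species)


def branch_incidence_from_arrays(
    arr: TreeArrays, site_by_species: np.ndarray, species: list[str]
) -> BranchIncidence:
    sp_pos = {s: j for j, s in enumerate(species)}
    try:
        cols = [sp_pos[lab] for lab in arr.tip_labels]
    except KeyError as exc:
        raise PartitionError(f"tree tip {exc} missing from composition") from None
    site_by_tip = site_by_species[:, cols]
    inc = site_by_tip @ arr.tip_branch_mask > 0
    return BranchIncidence(arr.branch_lengths, inc)
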