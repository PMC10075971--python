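"""Tip-shuffling null model and turnover/nestedness deviations.

For each focal cell the regional species pool is every species occurring in
the full moving window (focal plus all available neighbours, not a
subsample). Each null replicate draws a uniform random permutation of the
pool's labels over the tip positions of the pool-pruned tree — topology,
branch lengths and the composition matrix are untouched — and recomputes the
phylogenetic/functional turnover and nestedness on the *same* window
subsamples as the observed run. Per-cell richness, taxonomic beta-diversity
and the pool's total branch length are therefore conserved exactly; the
deviation is observed minus the null mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import CompositionGrid, GridError, neighborhood
from .partition import partition_subsets
from .trees import relabel_tips, tip_labels
from .windows import (
    WindowConfig,
    WindowContext,
    eligible_focals,
    facet_incidence,
    focal_rng,
    window_context,
)

_FACET_STREAM = {"phylogenetic": 1, "functional": 2}


@dataclass
class NullConfig:
    n_null: int = 200
    seed: int = 0
    report_sd: bool = True

    def __post_init__(self) -> None:
        if self.n_null < 1:
            raise GridError("n_null must be >= 1")


def regional_pool(comp: CompositionGrid, focal: str, cfg: WindowConfig) -> list[str]:
    """Union of species over the focal and all its available neighbours."""
    cells = [focal] + neighborhood(comp.cells, focal, cfg.radius)
    rows = [comp.cell_position(c) for c in cells]
    mask = comp.incidence[rows].any(axis=0)
    return [s for s, k in zip(comp.species, mask) if k]


def shuffle_tip_labels(tree, pool, rng: np.random.Generator):
    """Tree copy with the pool's labels uniformly permuted over the pool's tip
    positions; other tips, topology and branch lengths untouched."""
    pool = sorted(pool)
    have = set(tip_labels(tree))
    missing = sorted(set(pool) - have)
    if missing:
        raise GridError(f"pool species missing from tree: {missing[:5]}")
    perm = rng.permutation(len(pool))
    mapping = {pool[i]: pool[perm[i]] for i in range(len(pool))}
    return relabel_tips(tree, mapping)


DEVIATION_COLUMNS = (
    "cell_id",
    "facet",
    "component",
    "observed",
    "expected_mean",
    "expected_sd",
    "deviation",
)

_COMPONENT_KEY = {"turnover": "beta_sim", "nestedness": "beta_sne"}


def _null_facet(
    ctx: WindowContext, tree, facet: str, ncfg: NullConfig
) -> list[dict]:
    """Observed vs null-mean turnover/nestedness for one facet in one window."""
    inc, w, arr = facet_incidence(ctx, tree)
    obs_vals = partition_subsets(inc, w, ctx.subsets)
    # per-subset difference then mean: the identical arithmetic path as the
    # null replicates, so exchangeable trees give deviations of exactly zero
    obs = {
        "beta_sim": float(obs_vals["beta_sim"].mean()),
        "beta_sne": float((obs_vals["beta_sor"] - obs_vals["beta_sim"]).mean()),
    }

    n_tips = len(arr.tip_labels)
    pool_pos = {s: j for j, s in enumerate(ctx.pool)}
    tip_cols = np.array([pool_pos[lab] for lab in arr.tip_labels], dtype=np.intp)

    rng = focal_rng(ncfg.seed, ctx.focal, stream=_FACET_STREAM[facet])
    null_sim = np.empty(ncfg.n_null)
    null_sne = np.empty(ncfg.n_null)
    for r in range(ncfg.n_null):
        perm = rng.permutation(n_tips)
        # tip t takes the species of tip perm[t]: permuted labels, fixed topology
        site_by_tip = ctx.site_by_pool[:, tip_cols[perm]]
        b_inc = site_by_tip @ arr.tip_branch_mask > 0
        vals = partition_subsets(b_inc, arr.branch_lengths, ctx.subsets)
        null_sim[r] = vals["beta_sim"].mean()
        null_sne[r] = (vals["beta_sor"] - vals["beta_sim"]).mean()

    out = []
    for component, nulls in (("turnover", null_sim), ("nestedness", null_sne)):
        observed = obs[_COMPONENT_KEY[component]]
        # mean of identical replicates is that value (exact conservation when
        # the tree is label-exchangeable, e.g. a star)
        if np.all(nulls == nulls[0]):
            mean, sd = float(nulls[0]), 0.0
        else:
            mean, sd = float(nulls.mean()), float(nulls.std(ddof=1))
        out.append(
            {
                "cell_id": ctx.focal,
                "facet": facet,
                "component": component,
                "observed": observed,
                "expected_mean": mean,
                "expected_sd": sd,
                "deviation": observed - mean,
            }
        )
    return out


def null_expectation_and_deviation(
    comp: CompositionGrid,
    focal: str,
    wcfg: WindowConfig,
    ncfg: NullConfig,
    phylogeny=None,
    dendrogram=None,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Deviation records for one focal cell (phylogenetic and/or functional).

    Null permutations are drawn independently per facet; the window subsample
    sequence is shared with the observed computation so only tip identity
    varies.
    """
    ctx = window_context(comp, focal, wcfg, exhaustive=exhaustive)
    records = []
    for facet, tree in (("phylogenetic", phylogeny), ("functional", dendrogram)):
        if tree is None:
            continue
        records.extend(_null_facet(ctx, tree, facet, ncfg))
    return pd.DataFrame(records, columns=DEVIATION_COLUMNS)


def null_deviations(
    comp: CompositionGrid,
    wcfg: WindowConfig,
    ncfg: NullConfig,
    phylogeny=None,
    dendrogram=None,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Deviation records for every eligible focal cell."""
    frames = [
        null_expectation_and_deviation(
            comp, focal, wcfg, ncfg, phylogeny, dendrogram, exhaustive
        )
        for focal in eligible_focals(comp, wcfg)
    ]
    if not frames:
        return pd.DataFrame(columns=DEVIATION_COLUMNS)
    return pd.concat(frames, ignore_index=True)
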