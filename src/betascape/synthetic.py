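"""Synthetic gridded landscapes with a glacial-legacy causal structure.

The generator emulates the end-state patterns the analysis targets, on an
equal-area lattice whose row index plays the role of latitude:

* a climate-stability gradient: the "temperature anomaly" rises linearly from
  the first (stable, tropics-like) row to the last (unstable, formerly
  glaciated) row;
* a stable zone assembled from many small-ranged species placed independently
  of phylogeny (high spatial turnover);
* an unstable zone assembled from fewer, large-ranged species anchored at a
  refugium row, whose poleward range extents are phylogenetically conserved so
  that species drop out of assemblages in clade order (nested subsets, and
  phylogenetically/functionally selective loss);
* clade-geography coupling: unstable-zone species are drawn preferentially
  from a few young clades, so replacement there happens among close relatives;
* a handful of widespread species occupying every cell (richness floor);
* correlated environmental layers (current climate tracks the same gradient
  with independent noise) plus uncorrelated topography and human pressure.

Everything is driven by one seed and is bit-reproducible.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .grids import CompositionGrid, GridError
from .trees import phylo_vcv

TRAIT_NAMES = (
    "specific_leaf_area",
    "leaf_area",
    "leaf_dry_matter_content",
    "leaf_nitrogen",
    "leaf_phosphorus",
    "wood_density",
    "seed_dry_mass",
    "max_height",
)

# phylogenetic signal per trait; spread over the range typical for woody-plant
# functional traits (roughly 0.6-0.95)
DEFAULT_TRAIT_LAMBDAS = (0.95, 0.90, 0.85, 0.80, 0.75, 0.70, 0.65, 0.62)


@dataclass
class SyntheticConfig:
    n_rows: int = 16
    n_cols: int = 16
    cell_km: float = 200.0
    deg_per_row: float = 1.8  # 200 km of latitude

    anomaly_min: float = 0.5  # degC at the stable end
    anomaly_max: float = 8.0  # degC at the unstable end
    refugium_row: int = 8  # first unstable row; recolonization source

    n_stable_species: int = 140
    n_unstable_species: int = 42
    n_widespread_species: int = 6
    stable_range_rows: tuple[int, int] = (2, 4)  # block heights (inclusive)
    stable_range_cols: tuple[int, int] = (2, 4)
    stable_overhang_rows: int = 3  # how far stable ranges may cross the refugium line
    unstable_underhang_rows: int = 2  # how far refugium clades reach into the stable zone
    unstable_block_halfwidth: int = 1  # base column halfwidth of unstable ranges

    nestedness_strength: float = 0.9  # P(range is a refugium-anchored subset)
    clade_coupling: float = 0.9  # P(unstable species drawn from young clades)
    birth_rate: float = 1.0
    death_rate: float = 0.0

    trait_lambdas: tuple = DEFAULT_TRAIT_LAMBDAS
    anomaly_noise_sd: float = 1.5  # smooth (regional) anomaly variation
    anomaly_iid_sd: float = 0.4  # cell-scale anomaly variation
    mat_gradient: float = 1.5  # degC lost per row poleward
    mat_noise_sd: float = 4.0
    map_gradient: float = 150.0  # mm lost per row
    map_noise_sd: float = 450.0
    tseas_gradient: float = 0.9
    tseas_noise_sd: float = 2.5
    pseas_noise_sd: float = 10.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 9 or self.n_cols < 9:
            raise GridError("grid must be at least 9x9 for 5x5 windows")
        if not 0 <= self.nestedness_strength <= 1:
            raise GridError("nestedness_strength must be in [0, 1]")
        if not 0 <= self.clade_coupling <= 1:
            raise GridError("clade_coupling must be in [0, 1]")
        if not 0 < self.refugium_row < self.n_rows - 1:
            raise GridError("refugium_row must be interior")

    @property
    def n_species(self) -> int:
        return self.n_stable_species + self.n_unstable_species + self.n_widespread_species


@dataclass
class SyntheticDataset:
    comp: CompositionGrid
    phylogeny: dendropy.Tree
    traits: pd.DataFrame
    env: pd.DataFrame
    truth: dict = field(default_factory=dict)


def _cell_table(cfg: SyntheticConfig) -> pd.DataFrame:
    rows, cols = np.meshgrid(np.arange(cfg.n_rows), np.arange(cfg.n_cols), indexing="ij")
    rows, cols = rows.ravel(), cols.ravel()
    return pd.DataFrame(
        {
            "cell_id": [f"r{r:02d}c{c:02d}" for r, c in zip(rows, cols)],
            "row": rows,
            "col": cols,
            "x": cols * cfg.cell_km,
            "y": rows * cfg.cell_km,
            "latitude": rows * cfg.deg_per_row,
        }
    )


def simulate_phylogeny(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Pure-birth tree plus zone/clade assignments.

    With full clade-geography coupling, unstable-zone species are filled from
    the youngest clades (groups of mutually close relatives); with coupling 0
    the assignment is independent of the tree.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = cfg.n_species
    pyrng = _pyrandom.Random(int(rng.integers(0, 2**31 - 1)))
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=cfg.birth_rate,
        death_rate=cfg.death_rate,
        num_extant_tips=n,
        rng=pyrng,
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i + 1:04d}"

    # find disjoint young clades of moderate size: candidate internal nodes
    # sorted by crown age, greedily accepted if tip-disjoint from those chosen
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            depth[id(node)] = depth[id(node.parent_node)] + float(node.edge.length or 0.0)
    max_depth = max(depth.values())
    candidates = []
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd is tree.seed_node:
            continue
        tips = [lf.taxon.label for lf in nd.leaf_iter()]
        if 4 <= len(tips) <= 10:
            candidates.append((max_depth - depth[id(nd)], tips))
    candidates.sort(key=lambda t: t[0])  # youngest crown first

    taken: set[str] = set()
    clades: list[list[str]] = []
    for _, tips in candidates:
        if taken & set(tips):
            continue
        clades.append(tips)
        taken |= set(tips)
        if len(taken) >= cfg.n_unstable_species:
            break
    members = [s for clade in clades for s in clade][: cfg.n_unstable_species]
    clade_of = {}
    for ci, clade in enumerate(clades):
        for s in clade:
            if s in members:
                clade_of[s] = ci

    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    unassigned = set(labels) - set(members)
    # coupling < 1 dilutes the signal: a member's geographic role is handed to
    # a random unrelated species
    unstable, clade_id = [], []
    for s in members:
        if rng.random() < cfg.clade_coupling:
            pick = s
        else:
            others = sorted(unassigned)
            pick = others[rng.integers(len(others))]
            unassigned.discard(pick)
            unassigned.add(s)
        unstable.append(pick)
        clade_id.append(clade_of[s])
    rest = sorted(unassigned)
    widespread = [rest[i] for i in rng.choice(len(rest), cfg.n_widespread_species, replace=False)]
    unassigned -= set(widespread)
    stable = sorted(unassigned)

    zone = {s: "unstable" for s in unstable}
    zone.update({s: "stable" for s in stable})
    zone.update({s: "widespread" for s in widespread})
    cl = dict(zip(unstable, clade_id))
    assign = pd.DataFrame(
        {
            "species": labels,
            "zone": [zone[s] for s in labels],
            "clade": [cl.get(s, -1) for s in labels],
        }
    )
    return tree, assign


def _brownian(rng: np.random.Generator, C: np.ndarray, lam: float = 1.0) -> np.ndarray:
    """One draw from N(0, lambda-transformed C), scaled to unit variance."""
    diag = np.diag(C).copy()
    Cl = lam * (C - np.diag(diag)) + np.diag(diag)
    Cl = Cl / diag.mean() + 1e-9 * np.eye(len(C))
    L = np.linalg.cholesky(Cl)
    return L @ rng.standard_normal(len(C))


def simulate_traits(
    tree: dendropy.Tree,
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Traits evolved on the lambda-transformed tree, one lambda per trait.

    Values are exponentiated (base 10) so every trait is strictly positive and
    log-normally distributed, matching the log10-then-z transform convention.
    Each trait is an independent draw even under identical parameters.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    C, _ = phylo_vcv(tree, order=labels)
    cols = {}
    base = (1.2, 1.5, 2.3, 1.3, 0.2, -0.2, 1.0, 1.1)  # log10 typical magnitudes
    for name, lam, mu in zip(TRAIT_NAMES, cfg.trait_lambdas, base):
        x = _brownian(rng, C, lam)
        cols[name] = 10 ** (mu + 0.35 * x)
    return pd.DataFrame(cols, index=pd.Index(labels, name="species"))


def _assemble(cfg: SyntheticConfig, assign: pd.DataFrame,
              labels: list[str], anomaly: np.ndarray, rng: np.random.Generator):
    """Place species ranges on the grid; returns incidence and range truth.

    Ranges are rectangular blocks clipped by an anomaly tolerance: a species
    occupies a cell of its block only where the realized anomaly does not
    exceed its tolerance. Because the anomaly field has two-dimensional
    structure, range edges follow the field, not latitude, and composition
    responds to the local anomaly everywhere along the gradient.
    """
    n_rows, n_cols = cfg.n_rows, cfg.n_cols
    pos = {s: i for i, s in enumerate(labels)}
    inc = np.zeros((n_rows * n_cols, len(labels)), dtype=np.uint8)
    cell_of = lambda r, c: r * n_cols + c
    slope = (cfg.anomaly_max - cfg.anomaly_min) / (n_rows - 1)

    def tol_at(row: float) -> float:
        """Anomaly tolerance equal to the gradient value at a given row."""
        return cfg.anomaly_min + slope * row

    def fill(sp, r0, r1, c0, c1, a_min=None, a_max=None):
        r0, r1 = max(r0, 0), min(r1, n_rows - 1)
        c0, c1 = max(c0, 0), min(c1, n_cols - 1)
        for r in range(r0, r1 + 1):
            sl = slice(cell_of(r, c0), cell_of(r, c1) + 1)
            ok = np.ones(cell_of(r, c1) + 1 - cell_of(r, c0), dtype=bool)
            if a_max is not None:
                ok &= anomaly[sl] <= a_max
            if a_min is not None:
                ok &= anomaly[sl] >= a_min
            inc[sl, pos[sp]] |= ok.astype(np.uint8)

    zone = dict(zip(assign["species"], assign["zone"]))
    stable = [s for s in labels if zone[s] == "stable"]
    unstable = [s for s in labels if zone[s] == "unstable"]
    widespread = [s for s in labels if zone[s] == "widespread"]

    # widespread: everywhere (richness floor), tolerant of any anomaly
    for sp in widespread:
        fill(sp, 0, n_rows - 1, 0, n_cols - 1)

    # stable community: small blocks, placed independently of the tree; each
    # species draws an anomaly tolerance (most tolerate only mild anomalies)
    # and occupies its block only where the field stays below it. Blocks may
    # be drawn a few rows beyond the tolerance's gradient row, so locally mild
    # poleward pockets still host the small-ranged community.
    lo_r, hi_r = cfg.stable_range_rows
    lo_c, hi_c = cfg.stable_range_cols
    top_stable = cfg.refugium_row - 1 + cfg.stable_overhang_rows
    slack = 3
    for sp in stable:
        h = int(rng.integers(lo_r, hi_r + 1))
        w = int(rng.integers(lo_c, hi_c + 1))
        u = int(rng.integers(1, top_stable + 1))
        a_tol = tol_at(u + 0.5)
        r_hi = min(u + slack, n_rows - 1)
        r0 = int(rng.integers(-(h - 1), r_hi + 1))
        c0 = int(rng.integers(-(w - 1), n_cols))
        fill(sp, r0, r0 + h - 1, c0, c0 + w - 1, a_max=a_tol)

    # unstable zone: refugium-anchored ranges organised by young clade.
    # Each clade carries one anomaly tolerance (cold tolerance is conserved,
    # so species drop out of assemblages clade by clade as the anomaly rises
    # - phylogenetically clustered loss), and its members tile longitude in
    # adjacent sectors (parapatric sisters, so east-west replacement swaps
    # close relatives). More tolerant clades get wider blocks, keeping the
    # harshest areas dominated by a few tolerant, widespread lineages.
    n_unstable_rows = n_rows - cfg.refugium_row
    clade_members: dict[int, list[str]] = {}
    clade = dict(zip(assign["species"], assign["clade"]))
    for sp in unstable:
        clade_members.setdefault(clade[sp], []).append(sp)
    clade_ids = sorted(clade_members)
    n_clades = len(clade_ids)
    spaced = np.rint(np.linspace(1, n_unstable_rows, n_clades)).astype(int)
    clade_extent = dict(zip([clade_ids[i] for i in rng.permutation(n_clades)], spaced))
    r0_unstable = cfg.refugium_row - cfg.unstable_underhang_rows
    extents, anchored = {}, {}

    def _scatter(sp):
        # diluted signal: a plain range placed without refugium anchoring
        extent = int(rng.integers(1, n_unstable_rows + 1))
        r0 = int(rng.integers(cfg.refugium_row, n_rows - extent + 1))
        center = int(rng.integers(n_cols))
        shw = 2 + int(rng.integers(0, 3))
        fill(sp, r0, r0 + extent - 1, center - shw, center + shw,
             a_max=tol_at(r0 + extent - 0.5))
        anchored[sp] = False

    for ci in clade_ids:
        members = clade_members[ci]
        order = rng.permutation(len(members))
        sector = n_cols / len(members)
        E = int(clade_extent[ci])
        hw = cfg.unstable_block_halfwidth + E
        a_top = tol_at(cfg.refugium_row + E - 0.5)
        for slot, j in enumerate(order):
            sp = members[j]
            if rng.random() < cfg.nestedness_strength:
                # anchored ranges start below the refugium line (mixing band)
                # and reach poleward as far as the clade's anomaly tolerance
                # allows: the poleward edge follows the 2-D field
                center = int((slot + 0.5) * sector)
                fill(sp, r0_unstable, n_rows - 1, center - hw, center + hw,
                     a_max=a_top)
                anchored[sp] = True
            else:
                _scatter(sp)
            extents[sp] = E

    truth_ranges = pd.DataFrame(
        {
            "species": labels,
            "zone": [zone[s] for s in labels],
            "extent": [extents.get(s, np.nan) for s in labels],
            "refugium_anchored": [anchored.get(s, False) for s in labels],
        }
    )
    return inc, truth_ranges


def _interp_surface(rng, n_rows: int, n_cols: int, coarse: int) -> np.ndarray:
    knots = rng.standard_normal((coarse + 1, coarse + 1))
    ri = np.linspace(0, coarse, n_rows)
    ci = np.linspace(0, coarse, n_cols)
    r0 = np.clip(ri.astype(int), 0, coarse - 1)
    c0 = np.clip(ci.astype(int), 0, coarse - 1)
    fr = (ri - r0)[:, None]
    fc = (ci - c0)[None, :]
    return (
        knots[np.ix_(r0, c0)] * (1 - fr) * (1 - fc)
        + knots[np.ix_(r0 + 1, c0)] * fr * (1 - fc)
        + knots[np.ix_(r0, c0 + 1)] * (1 - fr) * fc
        + knots[np.ix_(r0 + 1, c0 + 1)] * fr * fc
    )


def _smooth_field(rng, n_rows: int, n_cols: int) -> np.ndarray:
    """Unit-variance random surface mixing a broad and an intermediate scale
    (bilinear interpolation of coarse iid grids). Unlike iid noise it survives
    5x5 window averaging, so environmental layers stay distinguishable after
    neighbourhood smoothing and retain variation at the scales the spatial
    error model does not absorb."""
    f = _interp_surface(rng, n_rows, n_cols, 3) + _interp_surface(rng, n_rows, n_cols, 7)
    return ((f - f.mean()) / f.std()).ravel()


def _anomaly_field(cfg: SyntheticConfig, rng) -> np.ndarray:
    """Realized anomaly per cell: latitudinal gradient plus a smooth field.

    This single field both drives the assembly (range clipping) and is what
    the environment table reports, so regression sees the true driver."""
    row = np.repeat(np.arange(cfg.n_rows, dtype=float), cfg.n_cols)
    slope = (cfg.anomaly_max - cfg.anomaly_min) / (cfg.n_rows - 1)
    grad = cfg.anomaly_min + slope * row
    return (
        grad
        + cfg.anomaly_noise_sd * _smooth_field(rng, cfg.n_rows, cfg.n_cols)
        + cfg.anomaly_iid_sd * rng.standard_normal(len(row))
    )


def _environment(cfg: SyntheticConfig, cells: pd.DataFrame, anomaly: np.ndarray,
                 rng) -> pd.DataFrame:
    row = cells["row"].to_numpy(float)
    nr, nc = cfg.n_rows, cfg.n_cols
    smooth = lambda: _smooth_field(rng, nr, nc)
    env = pd.DataFrame({"cell_id": cells["cell_id"]})
    env["temperature_anomaly"] = anomaly
    env["precipitation_anomaly"] = np.clip(50 + 15 * row + 60 * smooth(), 0, None)
    env["mat"] = 28.0 - cfg.mat_gradient * row + cfg.mat_noise_sd * smooth()
    env["map"] = np.clip(
        2400.0 - cfg.map_gradient * row + cfg.map_noise_sd * smooth(), 50, None
    )
    env["temp_seasonality"] = np.clip(
        2.0 + cfg.tseas_gradient * row + cfg.tseas_noise_sd * smooth(), 0.1, None
    )
    env["precip_seasonality"] = np.clip(25.0 + cfg.pseas_noise_sd * smooth(), 1.0, None)
    env["elev_range"] = np.clip(10 ** (2.5 + 0.5 * smooth()), 10, 4000)
    env["human_modification"] = np.clip(0.29 + 0.18 * smooth(), 0.0, 1.0)
    return env


def simulate_landscape(
    cfg: SyntheticConfig,
    phylogeny: dendropy.Tree | None = None,
    assignments: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[CompositionGrid, pd.DataFrame, dict]:
    """Composition grid, environment table and truth record for one landscape.

    Simulates its own phylogeny unless one (with assignments) is provided.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if phylogeny is None or assignments is None:
        phylogeny, assignments = simulate_phylogeny(cfg, rng)
    labels = assignments["species"].tolist()
    cells = _cell_table(cfg)
    anomaly = _anomaly_field(cfg, rng)
    inc, truth_ranges = _assemble(cfg, assignments, labels, anomaly, rng)
    env = _environment(cfg, cells, anomaly, rng)

    present = inc.any(axis=0)
    comp = CompositionGrid(
        cells=cells,
        species=[s for s, k in zip(labels, present) if k],
        incidence=inc[:, present],
    )
    if (comp.richness() < 5).any():
        raise GridError("synthetic configuration yields cells below 5 species")
    truth = {
        "anomaly_true": pd.DataFrame(
            {"cell_id": cells["cell_id"], "anomaly_true": anomaly}
        ),
        "species": truth_ranges.merge(assignments, on=["species", "zone"], how="left"),
        "phylogeny": phylogeny,
    }
    return comp, env, truth


def simulate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Full synthetic dataset: composition, phylogeny, traits, environment."""
    rng = np.random.default_rng(cfg.seed)
    phylogeny, assignments = simulate_phylogeny(cfg, rng)
    comp, env, truth = simulate_landscape(cfg, phylogeny, assignments, rng)
    traits = simulate_traits(phylogeny, cfg, rng)
    truth["config"] = asdict(cfg)
    return SyntheticDataset(
        comp=comp, phylogeny=phylogeny, traits=traits, env=env, truth=truth
    )
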