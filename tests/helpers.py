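"""Shared test utilities: brute-force oracles and small builders.

The multi-site oracle here is deliberately naive (python sets, pairwise
enumeration) and independent of the package's vectorised implementation.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from betascape.grids import CompositionGrid


def brute_force_components(incidence, weights=None):
    """Set-based multi-site components: S_i, S_T, a_M, sum_min, sum_max."""
    inc = np.asarray(incidence).astype(bool)
    n_sites, n_units = inc.shape
    w = np.ones(n_units) if weights is None else np.asarray(weights, float)
    sites = [set(np.nonzero(row)[0]) for row in inc]
    S = [sum(w[u] for u in s) for s in sites]
    union = set().union(*sites)
    S_T = sum(w[u] for u in union)
    a_m = sum(S) - S_T
    sum_min = sum_max = 0.0
    for i, j in combinations(range(n_sites), 2):
        b_ij = sum(w[u] for u in sites[i] - sites[j])
        b_ji = sum(w[u] for u in sites[j] - sites[i])
        sum_min += min(b_ij, b_ji)
        sum_max += max(b_ij, b_ji)
    return S, S_T, a_m, sum_min, sum_max


def brute_force_partition(incidence, weights=None):
    """Multi-site Sorensen / Simpson / nestedness from the naive components."""
    _, _, a_m, sum_min, sum_max = brute_force_components(incidence, weights)
    beta_sim = sum_min / (sum_min + a_m)
    beta_sor = (sum_min + sum_max) / (2 * a_m + sum_min + sum_max)
    return beta_sor, beta_sim, beta_sor - beta_sim


def pairwise_sorensen_simpson(site_a, site_b):
    """Classical two-site indices from species sets."""
    a = len(site_a & site_b)
    b = len(site_a - site_b)
    c = len(site_b - site_a)
    sor = (b + c) / (2 * a + b + c)
    sim = min(b, c) / (a + min(b, c))
    return sor, sim


def make_cells(n_rows: int, n_cols: int, cell_km: float = 200.0) -> pd.DataFrame:
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    rows, cols = rows.ravel(), cols.ravel()
    return pd.DataFrame(
        {
            "cell_id": [f"r{r}c{c}" for r, c in zip(rows, cols)],
            "row": rows,
            "col": cols,
            "x": cols * cell_km,
            "y": rows * cell_km,
            "latitude": rows * 1.8,
        }
    )


def make_grid(incidence, species=None, n_cols=None) -> CompositionGrid:
    """CompositionGrid on a synthetic lattice shaped to fit the row count."""
    inc = np.asarray(incidence, dtype=np.uint8)
    n = inc.shape[0]
    if n_cols is None:
        n_cols = int(np.ceil(np.sqrt(n)))
    n_rows = int(np.ceil(n / n_cols))
    cells = make_cells(n_rows, n_cols).iloc[:n].reset_index(drop=True)
    if species is None:
        species = [f"sp{j}" for j in range(inc.shape[1])]
    return CompositionGrid(cells=cells, species=list(species), incidence=inc)


def random_binary_matrix(rng, n_sites, n_units):
    """Random 0/1 matrix with no empty site and no empty unit column."""
    while True:
        inc = (rng.random((n_sites, n_units)) < rng.uniform(0.2, 0.8)).astype(np.uint8)
        if inc.sum(axis=1).min() > 0 and inc.sum(axis=0).min() > 0:
            return inc
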