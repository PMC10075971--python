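"""Gridded assemblage data: cell tables, binary composition grids, environment tables.

Assemblages live on an equal-area lattice: each cell has integer ``(row, col)``
indices, projected ``(x, y)`` coordinates in km, and a latitude in degrees.
Composition is a binary cells x species incidence matrix. Window adjacency is
defined on the integer indices (Chebyshev distance), not great-circle distance,
because moving windows are blocks of the lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CELL_COLUMNS = ("cell_id", "row", "col", "x", "y", "latitude")

ENV_COLUMNS = (
    "temperature_anomaly",
    "precipitation_anomaly",
    "mat",
    "map",
    "temp_seasonality",
    "precip_seasonality",
    "elev_range",
    "human_modification",
)


class GridError(ValueError):
    """Raised on contract violations in assemblage inputs."""


def validate_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Validate a cell table: required columns, unique cell_id and (row, col)."""
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise GridError(f"cell table missing columns: {missing}")
    if cells["cell_id"].duplicated().any():
        raise GridError("duplicate cell_id in cell table")
    if cells.duplicated(subset=["row", "col"]).any():
        raise GridError("duplicate (row, col) in cell table")
    out = cells.loc[:, list(CELL_COLUMNS)].reset_index(drop=True)
    out["cell_id"] = out["cell_id"].astype(str)
    out[["row", "col"]] = out[["row", "col"]].astype(int)
    return out


def read_cells(path) -> pd.DataFrame:
    return validate_cells(pd.read_csv(path))


def write_cells(cells: pd.DataFrame, path) -> None:
    cells.loc[:, list(CELL_COLUMNS)].to_csv(path, index=False)


@dataclass
class CompositionGrid:
    """Binary cells x species incidence with aligned cell metadata.

    ``incidence`` row *i* describes ``cells.iloc[i]``; columns follow
    ``species`` order. Entries are 0/1; every species column must have at
    least one presence.
    """

    cells: pd.DataFrame
    species: list[str]
    incidence: np.ndarray
    _cell_pos: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.cells = validate_cells(self.cells)
        self.species = [str(s) for s in self.species]
        if len(set(self.species)) != len(self.species):
            raise GridError("duplicate species identifiers")
        inc = np.asarray(self.incidence)
        if inc.shape != (len(self.cells), len(self.species)):
            raise GridError(
                f"incidence shape {inc.shape} does not match "
                f"{len(self.cells)} cells x {len(self.species)} species"
            )
        if not np.isin(inc, (0, 1)).all():
            raise GridError("non-binary incidence")
        inc = inc.astype(np.uint8)
        if inc.shape[1] and not inc.any(axis=0).all():
            empty = [s for s, ok in zip(self.species, inc.any(axis=0)) if not ok]
            raise GridError(f"species with no presences: {empty[:5]}")
        self.incidence = inc
        self._cell_pos = {c: i for i, c in enumerate(self.cells["cell_id"])}

    @property
    def n_cells(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_species(self) -> int:
        return self.incidence.shape[1]

    def cell_position(self, cell_id: str) -> int:
        try:
            return self._cell_pos[cell_id]
        except KeyError:
            raise GridError(f"unknown cell_id {cell_id!r}") from None

    def richness(self) -> np.ndarray:
        """Species count per cell, aligned with ``cells`` rows."""
        return self.incidence.sum(axis=1).astype(int)

    def species_at(self, cell_id: str) -> list[str]:
        row = self.incidence[self.cell_position(cell_id)]
        return [s for s, v in zip(self.species, row) if v]

    def to_wide(self) -> pd.DataFrame:
        df = pd.DataFrame(self.incidence, columns=self.species)
        df.insert(0, "cell_id", self.cells["cell_id"].to_numpy())
        return df


def read_composition(path, cells: pd.DataFrame, layout: str = "wide") -> CompositionGrid:
    """Read a composition CSV in wide or long layout.

    Wide: first column ``cell_id``, one column per species, entries "0"/"1".
    Long: columns ``cell_id, species``, one row per presence. Both layouts of
    the same data yield identical grids.
    """
    cells = validate_cells(cells)
    if layout == "wide":
        df = pd.read_csv(path, dtype={0: str})
        df = df.rename(columns={df.columns[0]: "cell_id"})
        species = [str(c) for c in df.columns[1:]]
        inc = df.iloc[:, 1:].to_numpy()
        if not np.isin(inc, (0, 1)).all():
            raise GridError("non-binary incidence")
        return CompositionGrid(
            cells=cells, species=species, incidence=_reindex(inc, df["cell_id"], cells)
        )
    if layout == "long":
        df = pd.read_csv(path, dtype=str)
        df = df.rename(columns=dict(zip(df.columns[:2], ("cell_id", "species"))))
        if df.duplicated(subset=["cell_id", "species"]).any():
            raise GridError("duplicate (cell, species) pairs in long layout")
        species = sorted(df["species"].unique())
        sp_pos = {s: j for j, s in enumerate(species)}
        known = set(cells["cell_id"])
        unknown = set(df["cell_id"]) - known
        if unknown:
            raise GridError(f"cell_id absent from cell table: {sorted(unknown)[:5]}")
        inc = np.zeros((len(cells), len(species)), dtype=np.uint8)
        pos = {c: i for i, c in enumerate(cells["cell_id"])}
        for c, s in zip(df["cell_id"], df["species"]):
            inc[pos[c], sp_pos[s]] = 1
        return CompositionGrid(cells=cells, species=species, incidence=inc)
    raise GridError(f"unknown layout {layout!r}")


def _align_cells(ids: pd.Series, cells: pd.DataFrame) -> np.ndarray:
    pos = {c: i for i, c in enumerate(cells["cell_id"])}
    unknown = [c for c in ids if c not in pos]
    if unknown:
        raise GridError(f"cell_id absent from cell table: {unknown[:5]}")
    return np.array([pos[c] for c in ids])


def _reindex(inc: np.ndarray, ids: pd.Series, cells: pd.DataFrame) -> np.ndarray:
    """Reorder wide-matrix rows into cell-table order."""
    if len(ids) != len(cells):
        raise GridError(
            f"composition has {len(ids)} rows but cell table has {len(cells)}"
        )
    pos = _align_cells(ids, cells)
    out = np.zeros_like(inc)
    out[pos] = inc
    return out


def write_composition(comp: CompositionGrid, path, layout: str = "wide") -> None:
    if layout == "wide":
        comp.to_wide().to_csv(path, index=False)
    elif layout == "long":
        rows, cols = np.nonzero(comp.incidence)
        pd.DataFrame(
            {
                "cell_id": comp.cells["cell_id"].to_numpy()[rows],
                "species": np.asarray(comp.species)[cols],
            }
        ).to_csv(path, index=False)
    else:
        raise GridError(f"unknown layout {layout!r}")


def filter_min_richness(comp: CompositionGrid, min_species: int = 5) -> CompositionGrid:
    """Drop cells with fewer than ``min_species`` species, then drop emptied
    species columns. Idempotent; errors if no cell survives."""
    if min_species < 1:
        raise GridError("min_species must be >= 1")
    keep = comp.richness() >= min_species
    if not keep.any():
        raise GridError("empty grid after filter")
    inc = comp.incidence[keep]
    sp_keep = inc.any(axis=0)
    return CompositionGrid(
        cells=comp.cells.loc[keep].reset_index(drop=True),
        species=[s for s, k in zip(comp.species, sp_keep) if k],
        incidence=inc[:, sp_keep],
    )


def neighborhood(cells: pd.DataFrame, focal: str, radius: int = 2) -> list[str]:
    """Cells (excluding the focal) within Chebyshev distance ``radius`` of the
    focal's (row, col), restricted to cells present in the table.

    radius=2 gives at most 24 neighbours (5x5 window), radius=1 at most 8.
    """
    if radius < 1:
        raise GridError("radius must be >= 1")
    cells = validate_cells(cells)
    hit = cells["cell_id"] == str(focal)
    if not hit.any():
        raise GridError(f"unknown focal cell {focal!r}")
    r0, c0 = cells.loc[hit, ["row", "col"]].iloc[0]
    cheb = np.maximum((cells["row"] - r0).abs(), (cells["col"] - c0).abs())
    sel = (cheb <= radius) & ~hit
    sub = cells.loc[sel].sort_values(["row", "col"])
    return sub["cell_id"].tolist()


def validate_env(env: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("cell_id", *ENV_COLUMNS) if c not in env.columns]
    if missing:
        raise GridError(f"environment table missing columns: {missing}")
    out = env.loc[:, ["cell_id", *ENV_COLUMNS]].reset_index(drop=True)
    out["cell_id"] = out["cell_id"].astype(str)
    hm = out["human_modification"]
    if ((hm < 0) | (hm > 1)).any():
        raise GridError("human_modification outside [0, 1]")
    if (out["elev_range"] < 0).any():
        raise GridError("negative elev_range")
    return out


def read_env(path) -> pd.DataFrame:
    return validate_env(pd.read_csv(path))


def write_env(env: pd.DataFrame, path) -> None:
    validate_env(env).to_csv(path, index=False)
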