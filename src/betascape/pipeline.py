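"""End-to-end orchestration: simulate -> dendrogram -> beta -> nullmodel -> attribute.

Each stage reads the previous stage's CSV/Newick artifacts from the run
directory and writes its own, so later stages can be re-run from cached
artifacts with identical results. A JSON manifest records the configuration,
seed and per-stage row counts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .grids import (
    read_cells,
    read_composition,
    read_env,
    write_cells,
    write_composition,
    write_env,
    filter_min_richness,
)
from .nullmodel import NullConfig, null_deviations
from .spatial import (
    multimodel_average,
    prepare_covariates,
    select_neighbor_distance,
    standardize,
    weights_from_cells,
)
from .synthetic import SyntheticConfig, simulate_dataset
from .traits import build_functional_dendrogram, read_traits, trait_pca, transform_traits, write_traits
from .trees import read_newick, write_newick
from .windows import WindowConfig, windowed_beta

log = logging.getLogger("betascape")

STAGES = ("simulate", "dendrogram", "beta", "nullmodel", "attribute")


@dataclass
class RunConfig:
    out_dir: str = "betascape_run"
    seed: int = 0
    radius: int = 2
    n_reps: int = 200
    n_null: int = 200
    retain_variance: float = 0.90
    min_richness: int = 5
    distances: tuple = tuple(range(200, 1001, 100))
    select_distance: bool = True
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def window_config(self) -> WindowConfig:
        return WindowConfig.for_radius(self.radius, n_reps=self.n_reps, seed=self.seed)

    def null_config(self) -> NullConfig:
        return NullConfig(n_null=self.n_null, seed=self.seed)


def _paths(out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    return {
        "cells": out / "cells.csv",
        "composition": out / "composition.csv",
        "env": out / "env.csv",
        "phylogeny": out / "phylogeny.nwk",
        "traits": out / "traits.csv",
        "truth_species": out / "truth_species.csv",
        "truth_cells": out / "truth_cells.csv",
        "dendrogram": out / "dendrogram.nwk",
        "pca": out / "pca_summary.csv",
        "lambda": out / "lambda_signal.csv",
        "beta": out / "beta.csv",
        "deviations": out / "deviations.csv",
        "attribution": out / "attribution.csv",
        "distance_selection": out / "distance_selection.csv",
        "manifest": out / "manifest.json",
    }


def stage_simulate(cfg: RunConfig) -> int:
    p = _paths(cfg.out_dir)
    synth = cfg.synthetic
    if synth.seed != cfg.seed:
        synth = SyntheticConfig(**{**asdict(synth), "seed": cfg.seed})
    ds = simulate_dataset(synth)
    write_cells(ds.comp.cells, p["cells"])
    write_composition(ds.comp, p["composition"], layout="wide")
    write_env(ds.env, p["env"])
    write_newick(ds.phylogeny, p["phylogeny"])
    write_traits(ds.traits, p["traits"])
    ds.truth["species"].to_csv(p["truth_species"], index=False)
    ds.truth["anomaly_true"].to_csv(p["truth_cells"], index=False)
    return ds.comp.n_cells


def stage_dendrogram(cfg: RunConfig) -> int:
    p = _paths(cfg.out_dir)
    traits = read_traits(p["traits"])
    transformed = transform_traits(traits)
    scores = trait_pca(transformed, retain=cfg.retain_variance)
    dend = build_functional_dendrogram(scores)
    write_newick(dend, p["dendrogram"])
    if p["phylogeny"].exists():
        from .traits import lambda_report

        lambda_report(read_newick(p["phylogeny"]), transformed).to_csv(
            p["lambda"], index=False
        )
    pd.DataFrame(
        {
            "component": [f"PC{i + 1}" for i in range(len(scores.explained))],
            "explained_variance": scores.explained,
            "retained": [i < scores.k for i in range(len(scores.explained))],
        }
    ).to_csv(p["pca"], index=False)
    return scores.k


def _load_inputs(cfg: RunConfig):
    p = _paths(cfg.out_dir)
    cells = read_cells(p["cells"])
    comp = filter_min_richness(
        read_composition(p["composition"], cells, layout="wide"), cfg.min_richness
    )
    phylo = read_newick(p["phylogeny"])
    dend = read_newick(p["dendrogram"])
    return comp, phylo, dend


def stage_beta(cfg: RunConfig) -> int:
    p = _paths(cfg.out_dir)
    comp, phylo, dend = _load_inputs(cfg)
    records = windowed_beta(comp, cfg.window_config(), phylogeny=phylo, dendrogram=dend)
    records.to_csv(p["beta"], index=False)
    return len(records)


def stage_nullmodel(cfg: RunConfig) -> int:
    p = _paths(cfg.out_dir)
    comp, phylo, dend = _load_inputs(cfg)
    dev = null_deviations(
        comp, cfg.window_config(), cfg.null_config(), phylogeny=phylo, dendrogram=dend
    )
    dev.to_csv(p["deviations"], index=False)
    return len(dev)


def attribution_responses(beta: pd.DataFrame, deviations: pd.DataFrame) -> dict[str, pd.Series]:
    """Named response vectors indexed by cell_id, in a stable order."""
    out: dict[str, pd.Series] = {}
    for facet in ("taxonomic", "phylogenetic", "functional"):
        sub = beta[beta["facet"] == facet].set_index("cell_id")
        for metric in ("beta_sor", "beta_sim", "beta_sne", "prop_nestedness"):
            out[f"{facet}.{metric}"] = sub[metric]
    for facet in ("phylogenetic", "functional"):
        for component in ("turnover", "nestedness"):
            sub = deviations[
                (deviations["facet"] == facet) & (deviations["component"] == component)
            ].set_index("cell_id")
            out[f"{facet}.{component}_deviation"] = sub["deviation"]
    return out


def stage_attribute(cfg: RunConfig) -> int:
    p = _paths(cfg.out_dir)
    cells = read_cells(p["cells"])
    env = read_env(p["env"])
    beta = pd.read_csv(p["beta"])
    deviations = pd.read_csv(p["deviations"])
    responses = attribution_responses(beta, deviations)

    focals = beta[beta["facet"] == "taxonomic"]["cell_id"].tolist()
    X = prepare_covariates(env, cells, focals, radius=cfg.radius)
    fcells = cells.set_index("cell_id").loc[focals].reset_index()

    rows = []
    sel_rows = []
    W_cache: dict[float, object] = {}
    for name, series in responses.items():
        y = standardize(series.loc[focals].to_numpy(float))
        if cfg.select_distance:
            sel = select_neighbor_distance(y, X, fcells, cfg.distances)
            d = sel.best_distance
            sel_rows.append({"response": name, "distance": d,
                             "min_rsa": sel.table.set_index("distance").loc[d, "min_rsa"]})
        else:
            d = float(cfg.distances[0])
        if d not in W_cache:
            W_cache[d] = weights_from_cells(fcells, d)
        avg = multimodel_average(y, X, W_cache[d])
        for cov, row in avg.coefficients.iterrows():
            rows.append({"response": name, "covariate": cov, **row.to_dict(),
                         "distance": d})
    pd.DataFrame(rows).to_csv(p["attribution"], index=False)
    if sel_rows:
        pd.DataFrame(sel_rows).to_csv(p["distance_selection"], index=False)
    return len(rows)


_STAGE_FN = {
    "simulate": stage_simulate,
    "dendrogram": stage_dendrogram,
    "beta": stage_beta,
    "nullmodel": stage_nullmodel,
    "attribute": stage_attribute,
}


def run_pipeline(cfg: RunConfig, stages=STAGES) -> dict:
    """Run the requested stages in order; abort on the first failure.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": json.loads(json.dumps(asdict(cfg), default=str)),
        "stages": [],
    }
    for stage in stages:
        if stage not in _STAGE_FN:
            raise ValueError(f"unknown stage {stage!r}")
        t0 = time.perf_counter()
        log.info("stage %s: starting", stage)
        try:
            count = _STAGE_FN[stage](cfg)
        except Exception:
            log.exception("stage %s failed", stage)
            manifest["stages"].append({"name": stage, "status": "failed"})
            _write_manifest(cfg, manifest)
            raise
        dt = time.perf_counter() - t0
        log.info("stage %s: done in %.1fs (%d rows)", stage, dt, count)
        manifest["stages"].append(
            {"name": stage, "status": "ok", "rows": int(count), "seconds": round(dt, 2)}
        )
    _write_manifest(cfg, manifest)
    return manifest


def _write_manifest(cfg: RunConfig, manifest: dict) -> None:
    with open(_paths(cfg.out_dir)["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2)
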