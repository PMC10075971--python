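"""Moving-window beta-diversity across a synthetic glacial-legacy landscape.

Simulates a 16x16 gridded flora with a climate-stability gradient, then
computes the multi-site partition in 5x5 moving windows (13 of 24 neighbours
resampled 200 times per focal cell) and summarizes how turnover and
nestedness trade off along the gradient.
"""

from betascape import SyntheticConfig, WindowConfig, simulate_dataset, windowed_beta

ds = simulate_dataset(SyntheticConfig(seed=1))
print(f"landscape: {ds.comp.n_cells} cells, {ds.comp.n_species} species, "
      f"mean richness {ds.comp.richness().mean():.1f}")

cfg = WindowConfig.for_radius(2, n_reps=200, seed=1)
beta = windowed_beta(ds.comp, cfg)  # taxonomic facet only, for speed
print(f"windowed partitions for {beta['cell_id'].nunique()} focal cells")

bands = beta.merge(ds.comp.cells, on="cell_id").groupby("row")
summary = bands[["beta_sim", "beta_sne", "prop_nestedness"]].mean()
print("\nrow (equator -> pole): turnover, nestedness, nestedness share")
for row, vals in summary.iterrows():
    print(f"  row {row:2d}: beta_SIM={vals.beta_sim:.3f} "
          f"beta_SNE={vals.beta_sne:.3f} prop={vals.prop_nestedness:.2f}")
# turnover dominates where the past climate was stable (low rows); the
# nestedness share exceeds 0.5 toward the high-anomaly edge, where
# assemblages are subsets of the refugium flora
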