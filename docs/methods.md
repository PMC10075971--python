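# Methods

This note records the models, numerical choices and known limitations behind
`betascape`, in the order data flows through the pipeline.

## Data model

Assemblages live on an equal-area lattice. A cell table carries integer
`(row, col)` indices, projected `(x, y)` coordinates in km and a latitude in
degrees; the composition is a binary cells × species matrix validated on
construction (entries in {0,1}, unique identifiers, no empty species
column). Window adjacency is Chebyshev distance on `(row, col)` — moving
windows are blocks of the lattice, not great-circle neighbourhoods. Cells
with fewer than five species are dropped before analysis (default
`min_species = 5`), and species left without presences are dropped with
them; the filter is idempotent. Trees (phylogeny and functional dendrogram
alike) are rooted dendropy trees with non-negative branch lengths whose tips
are species identifiers; species present in a tree but absent from the
composition are allowed (the tree is pruned per window), while composition
species missing from a tree are an error for branch-based facets.

## Multi-site partition

All three facets run through one abstraction: sites × units incidence with
non-negative unit weights. Units are species (weight 1) or branches of the
window-pool-pruned tree (weight = branch length; a branch is present at a
site iff at least one descendant tip occurs there). From site totals S_i,
pool total S_T and pairwise exclusives b_ij the turnover component is
β_SIM = Σmin/(Σmin + a_M) with a_M = ΣS_i − S_T, the total is
β_SOR = (Σmin + Σmax)/(2a_M + Σmin + Σmax), and β_SNE = β_SOR − β_SIM. The
implementation computes the pairwise shared-weight matrix once per window
and gathers it for every resampled site subset, so hundreds of subsets cost
a few vectorised operations; a set-based brute-force oracle in the test
suite checks agreement to 1e-12 on random weighted matrices.

Pruning conventions: the pruned tree is rooted at the pool's most recent
common ancestor and the root node itself carries no branch (any edge above
the pool MRCA is excluded — it would be shared by all sites whenever
present, so only β magnitudes, not comparisons, could notice it). A
single-species pool degenerates to one branch whose length is that tip's
root-to-tip path in the source tree. Zero-length branches are permitted;
they contribute nothing to any total.

## Moving windows

A focal cell is eligible when its window retains at least `min_neighbors`
cells after filtering (13 of 24 for the 5×5 window; 5 of 8 for the 3×3
variant). Per replicate, `n_subsample` neighbours are drawn uniformly
without replacement from the *available* neighbours — eligibility admits
focals with 13–24 neighbours, so sampling from availability is the only
consistent reading — and the (n_subsample+1)-site partition, focal always
included, is computed for every facet on the identical site set and averaged
arithmetically over `n_reps = 200` replicates. When a focal has exactly
`n_subsample` neighbours the window is deterministic and replication is
skipped. The reported nestedness proportion is the ratio of averaged
components, not the average of per-replicate ratios, which avoids division
by near-zero totals. Each focal's generator is seeded from a stable hash of
(global seed, cell id), so serial, parallel and re-run executions agree
bit-for-bit.

## Null model

The regional pool is the union of species over the focal and all its
available window neighbours (the full window, never a subsample). Each null
replicate applies one uniform permutation of the pool's labels to the tip
positions of the pool-pruned tree; topology, branch lengths and the
composition matrix are untouched, so per-cell richness, taxonomic
beta-diversity and the pool's total branch length are conserved exactly.
Two deliberate choices: (1) the null reuses the observed run's window
subsample sequence, isolating the effect of tip identity; (2) the phylogeny
and the dendrogram are shuffled independently — no coupling between facet
nulls is assumed. The deviation is reported raw (observed − null mean), with
the null standard deviation alongside for users who want a standardized
effect size. Numerical detail: the observed value follows the identical
arithmetic path as each null replicate (per-subset difference, then mean),
so label-exchangeable trees (a star) give deviations of exactly zero rather
than one-ulp residues, and the null mean of identical replicates is returned
as that value.

## Functional space

Traits are log10-transformed (all by default; configurable per analysis) and
z-scored; constant or non-positive-under-log traits are rejected. PCA
retains the smallest number of components whose cumulative explained
variance reaches 0.90 (a fixed k can be forced); component signs are fixed
by making each axis's largest-magnitude loading positive so scores are
platform-reproducible. Species are clustered by complete linkage on
Euclidean distances between retained scores (scipy's implementation; its
tie handling is deterministic given input order, which is what the
determinism requirement actually needs), and merge heights become node
depths of an ultrametric dendrogram serialized as Newick.

Pagel's λ multiplies the off-diagonal Brownian covariance; the likelihood
profiles out the root state and rate analytically and searches λ on [0, 1]
by bounded scalar minimization (tolerance 1e-6), with both interval ends
checked explicitly and a likelihood-ratio test against λ = 0 (χ², 1 df — a
conservative convention at a boundary). A relative jitter (1e-9 of the mean
diagonal) keeps the factorization defined when zero-length terminal branches
make tips exactly exchangeable.

## Spatial attribution

Covariates are averaged over the focal cell and its available window
neighbours, then elevational range is log10-transformed and human
modification square-root-transformed, then each column is z-scored over the
focal cells; responses are z-scored too, so all reported coefficients are
standardized. Spatial weights are binary distance-band adjacency (0, d] on
the km coordinates, row-standardized; rows without neighbours make that
distance unusable. The SAR error likelihood is concentrated (β and σ²
profiled out) and searched over ρ within the eigenvalue bounds of W, using
the real spectrum of the similar symmetric matrix D^(−1/2)BD^(−1/2) for the
log-determinant, computed once per W. Coefficient standard errors are the
GLS ones conditional on ρ̂; ρ's standard error comes from the curvature of
the profile likelihood. AIC = 2k − 2logL with k counting coefficients, σ²
and ρ.

Moran's I is computed per annular distance class of width one grid step
(200 km), and minRSA sums |I| over the first 20 classes; classes without
pairs contribute zero and are flagged. Distance selection minimizes minRSA
with ties broken by lower AIC, then smaller distance. Multimodel inference
enumerates all covariate subsets (intercept always included), weights by
exp(−ΔAIC/2), averages coefficients conditionally on inclusion, reports
importance as the summed weight of containing models, and builds CIs from
the Burnham–Anderson unconditional variance over containing models. The
corrected correlation test estimates an effective sample size from the
product of the two variables' distance-class correlograms
(Clifford–Richardson), clamps it to [3, n], and refers r to a t distribution
with n_eff − 2 df. Piecewise latitudinal fits grid-search a single
continuous hinge over the 5th–95th latitude percentiles; the hinge model
nests the straight line, so its SSE never exceeds the linear fit's.

## Synthetic landscapes

The generator encodes end-state patterns, not forward glacial-cycle
dynamics. One realized anomaly field drives everything and is what the
environment table reports: a linear latitudinal gradient (0.5 °C at the
stable edge to 8 °C at the unstable edge of a 16×16 grid) plus a unit-
variance smooth surface mixing a broad and an intermediate scale (sd 1.5 °C)
plus cell-scale noise (sd 0.4 °C). Ranges are rectangular blocks clipped by
per-species anomaly tolerances, so range edges follow the field in two
dimensions rather than latitude alone:

* the **stable community** (140 species) draws small blocks (2–4 cells a
  side) and low tolerances, placed independently of the phylogeny — high
  turnover where the climate stayed mild;
* **young clades** (42 species in disjoint clades of 4–10 tips with the
  youngest crowns) anchor at a refugium line, reach two rows equatorward
  (the zone transition is a mixing band, not a break), and share a
  clade-level tolerance from an evenly spaced ladder; members tile longitude
  in sectors that widen with tolerance. Rising anomaly therefore removes
  whole clades (stems and internals included — phylogenetically clustered
  loss) while east–west movement swaps sector neighbours that are close
  relatives;
* **widespread species** (6) occupy every cell, keeping every assemblage at
  or above the five-species floor and giving pools a deep-lineage backbone;
* coupling and anchoring are probabilistic (defaults 0.9): the complement
  hands a clade's geographic role to a random species or scatters a range
  freely, diluting the signal the way incomplete niche conservatism would;
* traits evolve on the λ-transformed tree with per-trait λ from 0.62 to
  0.95 (the range typical of woody-plant functional traits) and are
  exponentiated so the log10-then-z convention applies; the other
  environmental layers are gradient + smooth-surface draws with noise scales
  chosen to keep their mutual correlations strong but below ~0.85.

What the generator does *not* emulate: occurrence error and range-map
uncertainty, trait missingness and imputation, real climate fields' full
spectrum of spatial scales, continents and coastlines, and alpha-diversity
gradients beyond those implied by the range construction. Passing tests on
these landscapes show the machinery recovers a known causal structure at
desk scale; they are not evidence about any particular empirical dataset.

## Known limitations

* **SAR coefficients for null-model deviations at desk scale.** On the
  default 16×16 landscape (~240 focal cells) the deviation fields are
  window-overlap-smooth, the fitted error coefficient sits near 0.98, and
  GLS whitening then weighs exactly the fine scales at which a 25-cell
  window statistic carries little causal variation — the whitened
  cross-moment approximates the curvature of the response–covariate
  cross-covariance, whose sign need not match the broad-scale association.
  In practice the model-averaged anomaly coefficients for the four deviation
  responses vary in sign across generator seeds even though their bivariate
  (corrected-t) associations are consistently signed as expected (turnover
  deviations negative, nestedness deviations positive). The beta-component
  responses, with stronger and multi-scale signal, do not suffer from this:
  their six anomaly signs are stable across seeds. Analyses of this kind at
  a few hundred cells should read the deviation SAR coefficients with that
  degeneracy in mind; the estimator itself passes parameter-recovery checks
  on data simulated from the SAR model.
* Moran distance classes are fixed-width annuli from the grid resolution;
  irregular cell spacings would warrant quantile-based classes.
* The λ likelihood uses ML (not REML) profiling of the root state and rate;
  for the tree sizes used here the difference is well inside the recovery
  tolerances.
* The CLI is a thin veneer: anything beyond stage orchestration (continental
  stratification, custom responses) is meant to be scripted against the
  library API, as the examples do.
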