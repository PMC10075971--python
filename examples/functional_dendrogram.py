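"""From a trait table to a functional dendrogram and phylogenetic signal.

Eight continuous traits are log10- and z-transformed, projected on principal
components (keeping >= 90% of the variance), and species are clustered by
complete linkage on Euclidean distances between the retained scores. Pagel's
lambda measures how strongly each trait tracks the phylogeny.
"""

from betascape import SyntheticConfig, simulate_dataset, trait_pca, transform_traits
from betascape.traits import build_functional_dendrogram, lambda_report
from betascape.trees import tip_labels

ds = simulate_dataset(SyntheticConfig(seed=4))
z = transform_traits(ds.traits)  # log10 then z-score, every trait
scores = trait_pca(z, retain=0.90)
cum = scores.explained[: scores.k].sum()
print(f"retained {scores.k} of {len(scores.explained)} components "
      f"({100 * cum:.1f}% of trait variance)")

dend = build_functional_dendrogram(scores)
print(f"functional dendrogram over {len(tip_labels(dend))} species "
      f"(ultrametric, complete linkage)")

report = lambda_report(ds.phylogeny, z)
print("\nphylogenetic signal (Pagel's lambda) per trait:")
for _, r in report.iterrows():
    print(f"  {r['trait']:<24s} lambda={r['lambda_hat']:.2f}  p={r['p_value']:.1e}")
# traits were evolved with lambda between 0.62 and 0.95, so estimates cluster
# in that range and every likelihood-ratio test rejects lambda = 0
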