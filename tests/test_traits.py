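import numpy as np
import pandas as pd
import pytest

from betascape.partition import branch_incidence, partition
from betascape.traits import (
    TraitError,
    build_functional_dendrogram,
    pagels_lambda,
    trait_pca,
    transform_traits,
)
from betascape.trees import phylo_vcv, root_to_tip_depths, star_tree
from betascape.synthetic import SyntheticConfig, simulate_phylogeny, simulate_traits
from helpers import make_grid


def test_log_z_transform_closed_form():
    raw = pd.DataFrame({"t": [10.0, 100.0, 1000.0]}, index=["a", "b", "c"])
    out = transform_traits(raw)  # log10 -> (1,2,3) -> z with sd(ddof=1)=1
    np.testing.assert_allclose(out["t"], [-1.0, 0.0, 1.0], atol=1e-12)


def test_transform_idempotent_on_standardized_input(rng):
    z = rng.standard_normal(40)
    z = (z - z.mean()) / z.std(ddof=1)
    df = pd.DataFrame({"t": z})
    out = transform_traits(df, log10=False)
    np.testing.assert_allclose(out["t"], z, atol=1e-12)


def test_transform_errors():
    with pytest.raises(TraitError, match="non-positive"):
        transform_traits(pd.DataFrame({"t": [1.0, -2.0]}))
    with pytest.raises(TraitError, match="zero-variance"):
        transform_traits(pd.DataFrame({"t": [5.0, 5.0, 5.0]}), log10=False)


def test_pca_rank_one_and_retention_rules(rng):
    x = rng.standard_normal(60)
    df = pd.DataFrame({"a": x, "b": 3 * x + 1})
    scores = trait_pca(transform_traits(df, log10=False), retain=0.9)
    assert scores.k == 1
    assert scores.explained[0] == pytest.approx(1.0, abs=1e-12)

    noisy = pd.DataFrame(rng.standard_normal((200, 6)))
    noisy.columns = [f"t{j}" for j in range(6)]
    z = transform_traits(noisy, log10=False)
    k_low = trait_pca(z, retain=0.5).k
    k_high = trait_pca(z, retain=0.95).k
    assert k_low <= k_high  # retention threshold is monotone
    assert trait_pca(z, retain=4).k == 4
    with pytest.raises(TraitError):
        trait_pca(z, retain=7)


def test_pca_sign_convention_is_deterministic(rng):
    df = pd.DataFrame(rng.standard_normal((50, 4)), columns=list("abcd"))
    z = transform_traits(df, log10=False)
    s1 = trait_pca(z, retain=3).scores
    s2 = trait_pca(z.iloc[::-1].iloc[::-1], retain=3).scores
    pd.testing.assert_frame_equal(s1, s2)


def merge_heights(tree):
    """Tip-pair MRCA heights (ultrametric) from the BM covariance matrix."""
    C, labels = phylo_vcv(tree)
    depth = np.diag(C)
    heights = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            heights[(labels[i], labels[j])] = depth[i] - C[i, j]
    return heights


def test_dendrogram_hand_example():
    scores = pd.DataFrame({"PC1": [0.0, 1.0, 10.0]}, index=["a", "b", "c"])
    tree = build_functional_dendrogram(scores)
    h = merge_heights(tree)
    key_ab = ("a", "b") if ("a", "b") in h else ("b", "a")
    assert h[key_ab] == pytest.approx(1.0, abs=1e-9)
    others = [v for k, v in h.items() if k != key_ab]
    assert all(v == pytest.approx(10.0, abs=1e-9) for v in others)


def test_cophenetic_heights_dominate_input_distances(rng):
    pts = pd.DataFrame(rng.standard_normal((12, 3)), index=[f"s{i}" for i in range(12)])
    tree = build_functional_dendrogram(pts)
    h = merge_heights(tree)
    D = np.sqrt(((pts.values[:, None, :] - pts.values[None, :, :]) ** 2).sum(-1))
    idx = {f"s{i}": i for i in range(12)}
    for (a, b), height in h.items():
        assert height >= D[idx[a], idx[b]] - 1e-9  # complete linkage takes the max


def test_regular_simplex_dendrogram_behaves_as_star(rng):
    # three equidistant points: all merges at one height -> star reduction
    pts = pd.DataFrame(
        [[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]], index=["A", "B", "C"]
    )
    dend = build_functional_dendrogram(pts)
    inc = np.array([[1, 1, 0], [1, 0, 1], [0, 1, 1]], dtype=np.uint8)
    comp = make_grid(inc, species=["A", "B", "C"])
    bi = branch_incidence(dend, comp, ["A", "B", "C"])
    func = partition(bi.incidence, bi.branch_lengths, facet="functional")
    tax = partition(inc)
    assert func.beta_sor == pytest.approx(tax.beta_sor, abs=1e-12)
    assert func.beta_sim == pytest.approx(tax.beta_sim, abs=1e-12)


def test_dendrogram_needs_two_species():
    with pytest.raises(TraitError):
        build_functional_dendrogram(pd.DataFrame({"PC1": [1.0]}, index=["a"]))


def test_lambda_estimate_contract_and_recovery(rng):
    cfg = SyntheticConfig(seed=5)
    tree, _ = simulate_phylogeny(cfg, rng)
    C, labels = phylo_vcv(tree)
    L = np.linalg.cholesky(C / np.diag(C).mean() + 1e-9 * np.eye(len(C)))
    bm = pd.Series(L @ rng.standard_normal(len(C)), index=labels)
    iid = pd.Series(rng.standard_normal(len(C)), index=labels)
    est_bm = pagels_lambda(tree, bm)
    est_iid = pagels_lambda(tree, iid)
    for est in (est_bm, est_iid):
        assert 0.0 <= est.lambda_hat <= 1.0
    assert est_bm.lambda_hat > 0.7
    assert est_iid.lambda_hat < 0.3
    assert est_bm.p_value < 0.01  # strong signal vs lambda = 0


def test_lambda_input_validation(balanced_tree):
    with pytest.raises(TraitError, match="4 tips"):
        pagels_lambda(balanced_tree, pd.Series([1.0, 2.0], index=["A", "B"]))
    vals = pd.Series([1.0, 1.0, 1.0, 1.0], index=["A", "B", "C", "D"])
    with pytest.raises(TraitError, match="variance"):
        pagels_lambda(balanced_tree, vals)


def test_simulated_traits_track_their_lambdas(rng):
    cfg = SyntheticConfig(seed=3)
    tree, _ = simulate_phylogeny(cfg, rng)
    traits = simulate_traits(tree, cfg, rng)
    assert (traits > 0).all().all()
    # two traits with identical generating parameters are independent draws
    assert not traits.iloc[:, 0].equals(traits.iloc[:, 1])
    z = transform_traits(traits)
    high = pagels_lambda(tree, z["specific_leaf_area"])  # generated at 0.95
    assert high.lambda_hat > 0.6
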