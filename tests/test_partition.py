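import numpy as np
import pytest

from betascape.partition import (
    PartitionError,
    branch_incidence,
    multisite_components,
    nestedness_proportion,
    partition,
    partition_from_components,
    partition_subsets,
)
from betascape.trees import prune_to, root_to_tip_depths, tree_arrays
from helpers import (
    brute_force_components,
    brute_force_partition,
    make_grid,
    pairwise_sorensen_simpson,
    random_binary_matrix,
)

THREE_SITES = [[1, 1, 0, 0], [0, 1, 1, 0], [0, 0, 1, 1]]  # {1,2},{2,3},{3,4}
NESTED_PAIR = [[1, 1, 1, 1], [1, 1, 0, 0]]  # {1,2,3,4},{1,2}


def test_components_of_worked_examples():
    c = multisite_components(THREE_SITES)
    assert c.a_m == 2 and c.sum_min == 4 and c.sum_max == 4
    c = multisite_components(NESTED_PAIR)
    assert c.a_m == 2 and c.sum_min == 0 and c.sum_max == 2


def test_partition_of_worked_examples():
    p = partition(THREE_SITES)
    assert p.beta_sim == pytest.approx(2 / 3, abs=1e-15)
    assert p.beta_sne == pytest.approx(0, abs=1e-15)
    p = partition(NESTED_PAIR)
    assert p.beta_sim == 0
    assert p.beta_sor == pytest.approx(1 / 3, abs=1e-15)
    assert nestedness_proportion(p) == pytest.approx(1.0)


def test_identical_sites_give_zero_beta_and_flagged_proportion():
    p = partition([[1, 1, 0], [1, 1, 0]])
    assert (p.beta_sor, p.beta_sim, p.beta_sne) == (0, 0, 0)
    assert np.isnan(nestedness_proportion(p))


def test_empty_site_is_rejected():
    with pytest.raises(PartitionError, match="empty site"):
        multisite_components([[1, 0], [0, 0]])


def test_matches_brute_force_on_random_weighted_matrices(rng):
    for _ in range(100):
        n_sites = rng.integers(2, 7)
        n_units = rng.integers(2, 13)
        inc = random_binary_matrix(rng, n_sites, n_units)
        w = rng.uniform(0.1, 3.0, n_units)
        c = multisite_components(inc, w)
        S, S_T, a_m, s_min, s_max = brute_force_components(inc, w)
        np.testing.assert_allclose(c.site_totals, S, atol=1e-12)
        assert c.pool_total == pytest.approx(S_T, abs=1e-12)
        assert c.a_m == pytest.approx(a_m, abs=1e-12)
        assert c.sum_min == pytest.approx(s_min, abs=1e-12)
        assert c.sum_max == pytest.approx(s_max, abs=1e-12)
        p = partition_from_components(c)
        sor, sim, sne = brute_force_partition(inc, w)
        assert p.beta_sor == pytest.approx(sor, abs=1e-12)
        assert p.beta_sim == pytest.approx(sim, abs=1e-12)
        assert p.beta_sne == p.beta_sor - p.beta_sim  # additive by construction


def test_two_sites_reduce_to_classical_pairwise_indices(rng):
    for _ in range(50):
        inc = random_binary_matrix(rng, 2, 10)
        p = partition(inc)
        a = set(np.nonzero(inc[0])[0])
        b = set(np.nonzero(inc[1])[0])
        sor, sim = pairwise_sorensen_simpson(a, b)
        assert p.beta_sor == pytest.approx(sor, abs=1e-12)
        assert p.beta_sim == pytest.approx(sim, abs=1e-12)


def test_permutation_invariance(rng):
    inc = random_binary_matrix(rng, 5, 9)
    w = rng.uniform(0.5, 2.0, 9)
    p = partition(inc, w)
    rows = rng.permutation(5)
    cols = rng.permutation(9)
    q = partition(inc[rows][:, cols], w[cols])
    assert q.beta_sor == pytest.approx(p.beta_sor, abs=1e-14)
    assert q.beta_sim == pytest.approx(p.beta_sim, abs=1e-14)


def test_ubiquitous_unit_reduces_turnover_and_total(rng):
    for _ in range(20):
        inc = random_binary_matrix(rng, 4, 8)
        p = partition(inc)
        with_shared = np.column_stack([inc, np.ones(4, dtype=np.uint8)])
        q = partition(with_shared)
        assert q.beta_sor <= p.beta_sor + 1e-12
        if p.beta_sim > 0:
            assert q.beta_sim < p.beta_sim


def test_partition_subsets_consistent_with_single_calls(rng):
    inc = random_binary_matrix(rng, 8, 12)
    w = rng.uniform(0.2, 2.0, 12)
    subsets = np.array([rng.choice(8, size=4, replace=False) for _ in range(25)])
    vals = partition_subsets(inc, w, subsets)
    for r, rowset in enumerate(subsets):
        p = partition(inc[rowset], w)
        assert vals["beta_sor"][r] == pytest.approx(p.beta_sor, abs=1e-12)
        assert vals["beta_sim"][r] == pytest.approx(p.beta_sim, abs=1e-12)


def test_branch_incidence_worked_example(balanced_tree):
    # sites {A,B} vs {A,C}: phylo Simpson 1/3, taxonomic Simpson 1/2
    comp = make_grid([[1, 1, 0], [1, 0, 1]], species=["A", "B", "C"])
    bi = branch_incidence(balanced_tree, comp, ["A", "B", "C"])
    phylo = partition(bi.incidence, bi.branch_lengths, facet="phylogenetic")
    tax = partition(comp.incidence)
    assert phylo.beta_sim == pytest.approx(1 / 3, abs=1e-12)
    assert tax.beta_sim == pytest.approx(1 / 2, abs=1e-12)


def test_star_tree_partition_equals_taxonomic(star4, rng):
    inc = random_binary_matrix(rng, 4, 4)
    comp = make_grid(inc, species=["A", "B", "C", "D"])
    bi = branch_incidence(star4, comp, ["A", "B", "C", "D"])
    phylo = partition(bi.incidence, bi.branch_lengths, facet="phylogenetic")
    tax = partition(inc)
    assert phylo.beta_sor == tax.beta_sor
    assert phylo.beta_sim == tax.beta_sim


def test_pruning_preserves_path_lengths(balanced_tree):
    sub = prune_to(balanced_tree, ["A", "B"])
    arr = tree_arrays(sub)
    assert sorted(arr.tip_labels) == ["A", "B"]
    assert arr.total_length == pytest.approx(2.0)  # A-B path preserved
    # pruning to one side of the root keeps the internal edge collapsed
    sub2 = prune_to(balanced_tree, ["A", "C"])
    assert tree_arrays(sub2).total_length == pytest.approx(4.0)


def test_single_species_pool_uses_root_to_tip_path(balanced_tree):
    comp = make_grid([[1], [1]], species=["A"])
    bi = branch_incidence(balanced_tree, comp, ["A"])
    assert bi.branch_lengths == pytest.approx([2.0])
    assert root_to_tip_depths(balanced_tree)["A"] == pytest.approx(2.0)


def test_species_outside_pool_rejected(balanced_tree):
    comp = make_grid([[1, 1], [1, 1]], species=["A", "E"])
    with pytest.raises(PartitionError, match="outside pool|absent"):
        branch_incidence(balanced_tree, comp, ["A"])


try:
    from hypothesis import given, settings, strategies as st

    @st.composite
    def incidence_matrices(draw):
        n_sites = draw(st.integers(2, 5))
        n_units = draw(st.integers(2, 8))
        rows = st.lists(
            st.lists(st.integers(0, 1), min_size=n_units, max_size=n_units),
            min_size=n_sites, max_size=n_sites,
        )
        inc = np.array(draw(rows), dtype=np.uint8)
        # hypothesis may propose empty sites/units: repair minimally
        inc[inc.sum(axis=1) == 0, 0] = 1
        inc[:, inc.sum(axis=0) == 0] = 1
        return inc

    @given(incidence_matrices())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_partition_bounds_and_additivity_property(inc):
        p = partition(inc)
        assert 0 <= p.beta_sim <= p.beta_sor <= 1
        assert abs(p.beta_sor - p.beta_sim - p.beta_sne) < 1e-12
        sor, sim, _ = brute_force_partition(inc)
        assert p.beta_sor == pytest.approx(sor, abs=1e-12)
        assert p.beta_sim == pytest.approx(sim, abs=1e-12)

except ImportError:  # hypothesis is an optional test dependency
    pass
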