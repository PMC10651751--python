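"""Cluster-engine unit and property tests, including a brute-force oracle.

The oracle enumerates every group relabeling, computes t maps by the direct
formula and finds clusters with networkx connected components — fully
independent of the engine's vectorised/flood-fill implementation.
"""

from itertools import combinations, product

import networkx as nx
import numpy as np
import pytest
from scipy import stats as sps

from megfeedback import (ClusterConfig, chain_lattice, critical_t,
                         form_clusters, grid_lattice, permutation_test,
                         space_time_lattice, stat_map)


class TestCriticalT:
    def test_reported_threshold_anchors(self):
        assert round(critical_t(0.05, 73, 2), 2) == 1.99
        assert round(critical_t(0.001, 72, 2), 2) == 3.43

    def test_normal_limit(self):
        assert critical_t(0.05, 10_000_000, 2) == pytest.approx(1.96, abs=5e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            critical_t(1.5, 10, 2)
        with pytest.raises(ValueError):
            critical_t(0.05, 0, 2)
        with pytest.raises(ValueError):
            critical_t(0.05, 10, 3)


class TestStatMap:
    def test_identical_groups_give_zero_map(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((4, 10))
        with pytest.warns(RuntimeWarning):
            t = stat_map(a, a.copy())
        assert np.allclose(t, 0.0)

    def test_hand_computed_pooled_t(self):
        t = stat_map(np.array([[1.0], [2.0], [3.0]]),
                     np.array([[4.0], [5.0], [6.0]]))
        assert t[0] == pytest.approx(-3.674, abs=1e-3)

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal((5, 20)), rng.standard_normal((7, 20))
        assert np.allclose(stat_map(a, b), -stat_map(b, a))

    def test_matches_scipy_ttest(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal((6, 15)), rng.standard_normal((9, 15))
        expected = sps.ttest_ind(a, b, axis=0, equal_var=True).statistic
        assert np.allclose(stat_map(a, b), expected)

    def test_paired_matches_scipy(self):
        rng = np.random.default_rng(3)
        a, b = rng.standard_normal((8, 12)), rng.standard_normal((8, 12))
        expected = sps.ttest_rel(a, b, axis=0).statistic
        assert np.allclose(stat_map(a, b, "paired_t"), expected)

    def test_paired_requires_aligned_groups(self):
        with pytest.raises(ValueError):
            stat_map(np.zeros((3, 4)), np.zeros((5, 4)), "paired_t")

    def test_zero_variance_elements_get_t_zero(self):
        a = np.ones((3, 2))
        b = np.zeros((3, 2))
        with pytest.warns(RuntimeWarning):
            t = stat_map(a, b)
        assert np.all(t == 0.0)


class TestFormClusters:
    def test_subthreshold_map_yields_no_clusters(self):
        lat = chain_lattice(5)
        assert form_clusters(np.array([0.5, -1.0, 1.5, 0.0, -1.9]), 2.0, lat) == []

    def test_chain_example_masses(self):
        lat = chain_lattice(5)
        clusters = form_clusters(np.array([0.0, 3.0, 3.0, 0.0, 3.0]), 2.0, lat)
        assert sorted(c.mass for c in clusters) == [3.0, 6.0]
        assert all(c.sign == 1 for c in clusters)

    def test_opposite_signs_never_merge(self):
        lat = chain_lattice(2)
        clusters = form_clusters(np.array([3.0, -3.0]), 2.0, lat)
        assert len(clusters) == 2
        assert {c.sign for c in clusters} == {1, -1}

    def test_raising_threshold_never_grows_clusters(self):
        rng = np.random.default_rng(4)
        lat = grid_lattice(6, 8)
        tmap = rng.standard_normal(48) * 2
        low = form_clusters(tmap, 1.0, lat)
        high = form_clusters(tmap, 2.0, lat)
        assert sum(c.n_elements for c in high) <= sum(c.n_elements for c in low)
        members_high = set(np.concatenate(
            [c.element_indices for c in high])) if high else set()
        members_low = set(np.concatenate(
            [c.element_indices for c in low])) if low else set()
        assert members_high <= members_low

    def test_every_supra_element_in_exactly_one_cluster(self):
        rng = np.random.default_rng(5)
        lat = grid_lattice(5, 5)
        tmap = rng.standard_normal(25) * 2
        clusters = form_clusters(tmap, 1.5, lat)
        covered = np.concatenate([c.element_indices for c in clusters])
        assert len(covered) == len(set(covered))
        assert set(covered) == set(np.flatnonzero(np.abs(tmap) > 1.5))


# ---------------------------------------------------------------------------
# independent brute-force oracle

def _oracle_clusters(tmap, thr, graph):
    out = []
    for sign in (1, -1):
        supra = {i for i in graph if sign * tmap[i] > thr}
        sub = graph.subgraph(supra)
        for comp in nx.connected_components(sub):
            out.append((frozenset(comp), float(sum(tmap[i] for i in comp))))
    return out


def _oracle_t(a, b):
    na, nb = len(a), len(b)
    va = a.var(axis=0, ddof=1) * (na - 1)
    vb = b.var(axis=0, ddof=1) * (nb - 1)
    sp2 = (va + vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(0) - b.mean(0)) / denom
    return np.where(denom > 0, t, 0.0)


def _oracle_two_sample(a, b, thr, graph):
    """Exhaustive two-sample max-mass permutation test."""
    data = np.vstack([a, b])
    n, na = len(data), len(a)
    obs = _oracle_clusters(_oracle_t(a, b), thr, graph)
    null = []
    for picks in combinations(range(n), na):
        rest = [i for i in range(n) if i not in picks]
        t = _oracle_t(data[list(picks)], data[rest])
        cl = _oracle_clusters(t, thr, graph)
        null.append(max((abs(m) for _, m in cl), default=0.0))
    null = np.asarray(null)
    return {members: (mass, np.mean(null >= abs(mass) - 1e-12))
            for members, mass in obs}


def _graph_from_lattice(lat):
    g = nx.Graph()
    g.add_nodes_from(range(lat.n_elements))
    g.add_edges_from(zip(*lat.adjacency.nonzero()))
    return g


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_exhaustive_oracle_equivalence_two_sample(seed):
    """Engine masses and p-values equal full enumeration on tiny problems."""
    rng = np.random.default_rng(seed)
    lat = grid_lattice(3, 4)  # 12 elements
    a = rng.standard_normal((4, 12))
    b = rng.standard_normal((4, 12)) + 0.8
    cfg = ClusterConfig(t_threshold=1.5, n_permutations=10_000, seed=9)
    res = permutation_test(a, b, lat, cfg)
    assert res.exact  # C(8,4) = 70 labelings, fully enumerated
    oracle = _oracle_two_sample(a, b, 1.5, _graph_from_lattice(lat))
    assert len(res.clusters) == len(oracle)
    for c in res.clusters:
        key = frozenset(int(i) for i in c.element_indices)
        mass, p = oracle[key]
        assert c.mass == pytest.approx(mass, abs=1e-10)
        assert c.p_value == pytest.approx(p, abs=1e-12)


def test_exhaustive_oracle_equivalence_paired():
    rng = np.random.default_rng(7)
    lat = chain_lattice(10)
    a = rng.standard_normal((5, 10)) + 1.0
    b = rng.standard_normal((5, 10))
    cfg = ClusterConfig(stat="paired_t", t_threshold=2.0,
                        n_permutations=10_000, seed=1)
    res = permutation_test(a, b, lat, cfg)
    assert res.exact  # 2^5 = 32 sign patterns
    d = a - b
    graph = _graph_from_lattice(lat)

    def paired_t(x):
        sd = x.std(0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = x.mean(0) / (sd / np.sqrt(len(x)))
        return np.where(sd > 0, t, 0.0)

    null = []
    for signs in product((1.0, -1.0), repeat=5):
        cl = _oracle_clusters(paired_t(np.asarray(signs)[:, None] * d), 2.0, graph)
        null.append(max((abs(m) for _, m in cl), default=0.0))
    null = np.asarray(null)
    for c in res.clusters:
        expect_p = np.mean(null >= abs(c.mass) - 1e-12)
        assert c.p_value == pytest.approx(expect_p, abs=1e-12)


class TestPermutationTest:
    def test_identical_groups_give_empty_result(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal((5, 20))
        lat = chain_lattice(20)
        res = permutation_test(a, a.copy(), lat,
                               ClusterConfig(t_threshold=2.0, n_permutations=100))
        assert res.clusters == []
        assert res.min_p() == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        a = rng.standard_normal((10, 30))
        b = rng.standard_normal((12, 30)) + 0.7
        lat = chain_lattice(30)
        cfg = ClusterConfig(t_threshold=1.8, n_permutations=300, seed=5)
        r1 = permutation_test(a, b, lat, cfg)
        r2 = permutation_test(a, b, lat, cfg)
        assert np.array_equal(r1.null_max_mass, r2.null_max_mass)
        assert [c.p_value for c in r1.clusters] == [c.p_value for c in r2.clusters]

    def test_p_invariant_to_subject_order_when_exact(self):
        rng = np.random.default_rng(10)
        a = rng.standard_normal((4, 8))
        b = rng.standard_normal((4, 8)) + 1.2
        lat = chain_lattice(8)
        cfg = ClusterConfig(t_threshold=1.5, n_permutations=1000, seed=2)
        r1 = permutation_test(a, b, lat, cfg)
        r2 = permutation_test(a[::-1], b[[2, 0, 3, 1]], lat, cfg)
        assert sorted(c.p_value for c in r1.clusters) == \
            sorted(c.p_value for c in r2.clusters)

    def test_monte_carlo_p_uses_plus_one_estimator(self):
        rng = np.random.default_rng(11)
        a = rng.standard_normal((10, 10)) + 3.0
        b = rng.standard_normal((10, 10))
        lat = chain_lattice(10)
        res = permutation_test(a, b, lat,
                               ClusterConfig(t_threshold=2.0, n_permutations=99,
                                             seed=0))
        assert not res.exact
        for c in res.clusters:
            assert c.p_value >= 1 / 100
            assert c.p_value <= 1.0

    def test_planted_effect_detected_on_mesh(self, small_mesh, coarse_window):
        from megfeedback import EffectSpec, generate_source_epochs
        eff = EffectSpec(parcels=("parcel_2",), time_window_s=(0.2, 0.4),
                         amplitude_delta=2.0)
        n_times = coarse_window.times().size
        ga, gb = [], []
        for i in range(10):
            ga.append(generate_source_epochs(
                small_mesh, 25, None, seed=50 + i,
                window=coarse_window).data.mean(0))
            gb.append(generate_source_epochs(
                small_mesh, 25, eff, seed=150 + i,
                window=coarse_window).data.mean(0))
        lat = space_time_lattice(small_mesh, n_times)
        res = permutation_test(
            np.stack(ga).reshape(10, -1), np.stack(gb).reshape(10, -1), lat,
            ClusterConfig(cluster_alpha=0.05, n_permutations=500, seed=3))
        sig = res.significant()
        assert sig
        top = max(sig, key=lambda c: abs(c.mass))
        verts = np.unique(top.element_indices // n_times)
        planted = set(small_mesh.parcels["parcel_2"])
        assert len(planted & set(verts.tolist())) / len(planted) > 0.5

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ClusterConfig(tail="one_sided")
        with pytest.raises(ValueError):
            ClusterConfig(stat="median_test")
        with pytest.raises(ValueError):
            ClusterConfig(n_permutations=0)


def test_lattice_shapes_and_adjacency(small_mesh):
    lat = space_time_lattice(small_mesh, 7)
    assert lat.n_elements == small_mesh.n_vertices * 7
    # element (v, t) neighbours (v, t+1) but not (u, t+1) for u != v
    v0, v1 = small_mesh.edges[0]
    i = int(v0) * 7 + 3
    neighbours = set(lat.adjacency[i].nonzero()[1].tolist())
    assert i - 1 in neighbours and i + 1 in neighbours
    assert int(v1) * 7 + 3 in neighbours
    assert int(v1) * 7 + 4 not in neighbours

    grid = grid_lattice(3, 3)
    centre = 4
    assert set(grid.adjacency[centre].nonzero()[1].tolist()) == {1, 3, 5, 7}
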