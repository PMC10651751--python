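import numpy as np
import pytest

from conftest import make_chain_mesh
from megfeedback import (ClusterConfig, DegenerateBaselineError,
                         ROIFilterConfig, SourceEpochs, clusters_to_rois,
                         compare_learners, filter_clusters,
                         representative_stc, temporal_cluster_test,
                         toi_summary)
from megfeedback.cluster import Cluster


def _cluster(vertices, t_span, n_times, mass=100.0, p=0.01):
    """Space-time cluster covering given vertices over [t0, t1] samples."""
    t0, t1 = t_span
    elements = np.array([v * n_times + t
                         for v in vertices for t in range(t0, t1 + 1)])
    return Cluster(element_indices=elements, sign=1, mass=mass, p_value=p)


N_TIMES = 200
SFREQ = 1000.0  # 1 ms per sample: duration in ms == sample span


class TestFilterRules:
    mesh = make_chain_mesh(80)

    def _keep(self, cluster, cfg=None):
        return filter_clusters([cluster], self.mesh, N_TIMES, SFREQ, cfg)

    def test_fifteen_vertices_excluded(self):
        c = _cluster(range(15), (0, 100), N_TIMES)
        assert self._keep(c) == []

    def test_sixteen_vertices_and_25ms_survive(self):
        c = _cluster(range(16), (0, 25), N_TIMES)
        assert self._keep(c) == [c]

    def test_short_duration_excluded(self):
        c = _cluster(range(40), (0, 19), N_TIMES)
        assert self._keep(c) == []

    def test_twenty_ms_survives(self):
        c = _cluster(range(40), (0, 20), N_TIMES)
        assert self._keep(c) == [c]

    def test_small_area_excluded_even_with_many_vertices(self):
        cfg = ROIFilterConfig(min_vertices=5, min_area_cm2=2.29)
        c = _cluster(range(10), (0, 100), N_TIMES)  # 10 x 0.1527 = 1.527 cm2
        assert self._keep(c, cfg) == []

    def test_medial_wall_removed_before_counting(self):
        mesh = make_chain_mesh(80, medial=[i < 5 for i in range(80)])
        c = _cluster(range(20), (0, 100), N_TIMES)  # 15 non-medial vertices
        assert filter_clusters([c], mesh, N_TIMES, SFREQ) == []

    def test_filtering_idempotent_and_order_independent(self):
        keep = _cluster(range(30), (0, 50), N_TIMES)
        drop = _cluster(range(10), (0, 50), N_TIMES)
        once = self._keep(keep) + self._keep(drop)
        assert filter_clusters([drop, keep], self.mesh, N_TIMES, SFREQ) == once
        assert filter_clusters(once, self.mesh, N_TIMES, SFREQ) == once


class TestClusterToROI:
    labels = ["pA"] * 50 + ["pB"] * 30
    mesh = make_chain_mesh(80, labels=labels)
    loose = ROIFilterConfig(min_vertices=1, min_area_cm2=0.0)

    def test_full_parcel_coverage(self):
        c = _cluster(range(50), (0, 50), N_TIMES)
        rois = clusters_to_rois(c, self.mesh, N_TIMES, self.loose)
        assert len(rois) == 1
        assert rois[0].parcel_label == "pA"
        assert rois[0].coverage_percent == pytest.approx(100.0)

    def test_partial_coverage_arithmetic(self):
        c = _cluster(range(13), (0, 50), N_TIMES)
        rois = clusters_to_rois(c, self.mesh, N_TIMES, self.loose)
        assert rois[0].coverage_percent == pytest.approx(26.0)

    def test_cluster_spanning_two_parcels(self):
        c = _cluster(range(40, 60), (0, 50), N_TIMES)  # 10 in pA, 10 in pB
        rois = clusters_to_rois(c, self.mesh, N_TIMES, self.loose)
        assert {r.parcel_label for r in rois} == {"pA", "pB"}
        cov = {r.parcel_label: r.coverage_percent for r in rois}
        assert cov["pA"] == pytest.approx(100 * 10 / 50)
        assert cov["pB"] == pytest.approx(100 * 10 / 30)

    def test_small_fragments_dropped(self):
        cfg = ROIFilterConfig(min_vertices=16, min_area_cm2=0.0)
        c = _cluster(range(45, 65), (0, 50), N_TIMES)  # 5 in pA, 15 in pB
        assert clusters_to_rois(c, self.mesh, N_TIMES, cfg) == []

    def test_members_subset_of_parcel(self):
        c = _cluster(range(10, 55), (0, 50), N_TIMES)
        for r in clusters_to_rois(c, self.mesh, N_TIMES, self.loose):
            parcel = self.mesh.parcels[r.parcel_label]
            assert set(r.member_vertices) <= set(parcel)
            assert 0 < r.coverage_percent <= 100


def _epochs(data, sfreq=100.0):
    data = np.asarray(data, dtype=float)
    times = -0.25 + np.arange(data.shape[2]) / sfreq
    return SourceEpochs("s", "control", "positive", data, times, sfreq)


class TestRepresentativeSTC:
    def test_single_vertex_equals_zscored_trace(self):
        rng = np.random.default_rng(0)
        ep = _epochs(rng.standard_normal((20, 3, 50)))
        r = representative_stc(ep, [1])
        trace = ep.data[:, 1, :].mean(axis=0)
        mask = ep.times_s <= 0.0
        expect = (trace - trace[mask].mean()) / trace[mask].std(ddof=1)
        assert np.allclose(r, expect)

    def test_cancellation_raises_degenerate_baseline(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((5, 1, 40))
        data = np.concatenate([x, -x], axis=1)  # vertex traces x and -x
        with pytest.raises(DegenerateBaselineError):
            representative_stc(_epochs(data), [0, 1])

    def test_planted_ramp_recovered(self):
        rng = np.random.default_rng(2)
        n_t = 86
        times = -0.25 + np.arange(n_t) / 100.0
        ramp = np.where(times > 0, np.clip(times / 0.6, 0, 1) * 5.0, 0.0)
        data = rng.standard_normal((100, 4, n_t)) * 0.5 + ramp
        r = representative_stc(_epochs(data), [0, 1, 2, 3])
        post = times > 0.3
        assert r[post].mean() > 2.0
        assert abs(r[times <= 0].mean()) < 1e-10

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            representative_stc(_epochs(np.random.randn(3, 2, 30)), [])


class TestTOI:
    times = -0.25 + np.arange(85) / 100.0

    def test_constant_trace(self):
        assert toi_summary(np.full(85, 3.3), self.times, (0.1, 0.3)) == \
            pytest.approx(3.3)

    def test_mean_of_integer_ramp(self):
        # trace equal to the sample index over a 4-sample interval
        trace = np.zeros(85)
        i0 = int(np.argmin(np.abs(self.times - 0.1)))
        trace[i0:i0 + 4] = np.arange(4)
        interval = (self.times[i0], self.times[i0 + 3] + 0.005)
        assert toi_summary(trace, self.times, interval) == pytest.approx(1.5)

    def test_half_open_interval(self):
        trace = np.zeros(85)
        i0 = np.argmin(np.abs(self.times - 0.1))
        trace[i0] = 1.0
        # offset sample excluded, onset included
        assert toi_summary(trace, self.times, (0.1, 0.11)) == pytest.approx(1.0)
        assert toi_summary(trace, self.times, (0.11, 0.12)) == pytest.approx(0.0)

    def test_interval_outside_epoch_rejected(self):
        with pytest.raises(ValueError):
            toi_summary(np.zeros(85), self.times, (0.5, 0.9))
        with pytest.raises(ValueError):
            toi_summary(np.zeros(85), self.times, (0.1, 0.1))


class TestCompareLearners:
    def test_df_structure_for_36_19_split(self):
        rng = np.random.default_rng(3)
        values = rng.standard_normal(55)
        flags = np.array([True] * 36 + [False] * 19)
        res = compare_learners(values, flags)
        assert res["df"] == 53
        assert res["n_learners"] == 36 and res["n_nonlearners"] == 19

    def test_matches_pooled_t_formula(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([4.0, 5.0, 6.0])
        res = compare_learners(np.concatenate([x, y]),
                               np.array([True] * 3 + [False] * 3))
        assert res["t"] == pytest.approx(-3.674, abs=1e-3)
        assert res["mean_learners"] == 2.0 and res["mean_nonlearners"] == 5.0

    def test_small_subgroup_rejected(self):
        with pytest.raises(ValueError):
            compare_learners(np.arange(5.0), np.array([True] * 4 + [False]))


def test_temporal_cluster_test_identical_groups_empty():
    rng = np.random.default_rng(4)
    a = rng.standard_normal((6, 40))
    res = temporal_cluster_test(a, a.copy(),
                                ClusterConfig(t_threshold=2.0,
                                              n_permutations=100))
    assert res.clusters == []


def test_temporal_cluster_recovers_planted_offset_window():
    rng = np.random.default_rng(5)
    times = -0.25 + np.arange(85) / 100.0
    effect = np.where((times >= 0.3) & (times <= 0.5), 1.8, 0.0)
    a = rng.standard_normal((15, 85))
    b = rng.standard_normal((15, 85)) + effect
    res = temporal_cluster_test(
        a, b, ClusterConfig(cluster_alpha=0.05, n_permutations=500, seed=1))
    sig = res.significant()
    assert sig
    top = max(sig, key=lambda c: abs(c.mass))
    span = times[np.sort(top.element_indices)]
    assert span[0] < 0.5 and span[-1] > 0.3  # overlaps the planted window
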