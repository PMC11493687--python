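import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import erplocsim as els
from erplocsim.errors import InvalidArgumentError
from erplocsim.evaluate import EvalParams


def _estimate(csd, fs=250.0, t0=-200.0, cond=""):
    return els.SourceEstimate(csd=csd, fs=fs, t0_ms=t0, condition=cond)


def brute_force_components(positions, radius_m):
    """Oracle: connected components from the full pairwise distance matrix."""
    n = len(positions)
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=2)
    adj = d < radius_m
    labels = -np.ones(n, dtype=int)
    comp = 0
    for i in range(n):
        if labels[i] >= 0:
            continue
        stack = [i]
        labels[i] = comp
        while stack:
            k = stack.pop()
            for j in np.flatnonzero(adj[k]):
                if labels[j] < 0:
                    labels[j] = comp
                    stack.append(j)
        comp += 1
    return labels


class TestConditionDifference:
    def test_equal_conditions_give_zero(self):
        csd = np.abs(np.random.default_rng(0).standard_normal((20, 250)))
        diff = els.condition_difference(_estimate(csd), _estimate(csd))
        np.testing.assert_array_equal(diff, 0.0)

    def test_single_dipole_offset_recovered(self):
        noise = np.abs(np.random.default_rng(1).standard_normal((20, 250)))
        erp = noise.copy()
        erp[7] += 2.5
        diff = els.condition_difference(_estimate(erp), _estimate(noise))
        assert diff[7] == pytest.approx(2.5)
        others = np.delete(diff, 7)
        np.testing.assert_allclose(others, 0.0, atol=1e-12)

    def test_default_window_averages_31_samples_at_250hz(self):
        """100-220 ms inclusive at 250 Hz covers 31 samples."""
        csd = np.zeros((3, 250))
        t = -200.0 + np.arange(250) * 4.0
        csd[:, (t >= 100) & (t <= 220)] = 1.0
        n_in_window = int(((t >= 100) & (t <= 220)).sum())
        assert n_in_window == 31
        diff = els.condition_difference(_estimate(csd), _estimate(np.zeros_like(csd)))
        np.testing.assert_allclose(diff, 1.0)

    def test_window_outside_epoch_rejected(self):
        csd = np.zeros((3, 250))
        with pytest.raises(InvalidArgumentError):
            els.condition_difference(
                _estimate(csd), _estimate(csd), window_ms=(700.0, 900.0)
            )


class TestThreshold:
    def test_five_percent_of_100_is_5(self):
        vals = np.random.default_rng(0).standard_normal(100)
        mask = els.threshold_top_fraction(vals, 0.05)
        assert mask.sum() == 5

    def test_matches_sort_oracle(self):
        vals = np.random.default_rng(1).standard_normal(1000)
        mask = els.threshold_top_fraction(vals, 0.05)
        top = np.argsort(-vals)[:50]
        np.testing.assert_array_equal(np.flatnonzero(mask), np.sort(top))

    def test_all_equal_warns_and_uses_index_tiebreak(self):
        with pytest.warns(UserWarning):
            mask = els.threshold_top_fraction(np.zeros(100), 0.05)
        np.testing.assert_array_equal(np.flatnonzero(mask), np.arange(5))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        scale=st.floats(1e-6, 1e6),
        n=st.integers(20, 400),
    )
    def test_scale_invariance(self, seed, scale, n):
        vals = np.random.default_rng(seed).standard_normal(n)
        m1 = els.threshold_top_fraction(vals, 0.05)
        m2 = els.threshold_top_fraction(vals * scale, 0.05)
        np.testing.assert_array_equal(m1, m2)


def _grid_sources(spacing_mm=3.0):
    """Small flat 3D grid embedded at a fixed depth (z plane)."""
    xs = np.arange(-10, 11) * spacing_mm * 1e-3
    x, y = np.meshgrid(xs, xs)
    pos = np.column_stack([x.ravel(), y.ravel(), np.full(x.size, 0.05)])
    return els.SourceSpace(
        positions=pos,
        nominal_spacing_mm=spacing_mm,
        per_dipole_volume_mm3=spacing_mm**3,
    )


class TestClustering:
    def test_two_blobs_20mm_apart_make_two_clusters(self):
        src = _grid_sources()
        pos = src.positions
        c1 = np.array([-0.015, 0.0, 0.05])
        c2 = np.array([0.015, 0.0, 0.05])  # 30 mm apart on the plane
        mask = (np.linalg.norm(pos - c1, axis=1) < 0.005) | (
            np.linalg.norm(pos - c2, axis=1) < 0.005
        )
        cs = els.cluster_adjacent(mask, src, adjacency_mm=5.0, min_size=5)
        assert cs.n_clusters == 2

    def test_isolated_actives_are_dropped(self):
        src = _grid_sources()
        mask = np.zeros(src.n_dipoles, dtype=bool)
        mask[[0, 20, 420, 440]] = True  # far corners, pairwise > 5 mm
        cs = els.cluster_adjacent(mask, src, adjacency_mm=5.0, min_size=5)
        assert cs.n_clusters == 0

    def test_exactly_five_adjacent_dipoles_survive(self):
        src = _grid_sources()
        # a plus-shaped blob of 5 mutually connected dipoles
        center = 220  # middle of the 21x21 grid
        mask = np.zeros(src.n_dipoles, dtype=bool)
        mask[[center, center - 1, center + 1, center - 21, center + 21]] = True
        cs = els.cluster_adjacent(mask, src, adjacency_mm=5.0, min_size=5)
        assert cs.n_clusters == 1
        assert len(cs.clusters[0]) == 5
        assert cs.volumes_mm3[0] == 5 * 27.0

    def test_adjacency_is_strict_inequality(self):
        pos = np.array([[0.0, 0.0, 0.0], [0.005, 0.0, 0.0]])  # exactly 5 mm
        src = els.SourceSpace(pos, 5.0, 125.0)
        cs = els.cluster_adjacent(
            np.ones(2, dtype=bool), src, adjacency_mm=5.0, min_size=1
        )
        assert cs.n_clusters == 2  # 5 mm is NOT adjacent under d < 5 mm

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_components(self, seed):
        rng = np.random.default_rng(seed)
        src = _grid_sources()
        mask = rng.random(src.n_dipoles) < 0.08
        cs = els.cluster_adjacent(mask, src, adjacency_mm=5.0, min_size=1)
        active = np.flatnonzero(mask)
        labels = brute_force_components(src.positions[active], 0.005)
        sizes_oracle = sorted(np.bincount(labels)) if active.size else []
        sizes_mine = sorted(len(c) for c in cs.clusters)
        assert sizes_mine == sizes_oracle


def _net_with_centers(centers):
    rois = tuple(
        els.ROISpec(
            name=f"roi{i}",
            center=c,
            radius_mm=10.0,
            onset_ms=100.0,
            amplitude_scale=1.0,
        )
        for i, c in enumerate(centers)
    )
    return els.NetworkSpec(name="custom", rois=rois)


def _clusterset(centers, sizes, vol=27.0):
    return els.ClusterSet(
        clusters=[np.arange(s) for s in sizes],
        centers=np.asarray(centers, dtype=float),
        volumes_mm3=np.array([s * vol for s in sizes], dtype=float),
        threshold_used=0.0,
        params=EvalParams(),
    )


class TestClassification:
    ROIS = _net_with_centers(
        [[0.05, 0, 0], [0, 0.05, 0], [-0.05, 0, 0], [0, -0.05, 0]]
    )

    def test_three_of_four_rois_matched(self):
        offsets = np.array([[0.015, 0, 0], [0, 0.015, 0], [-0.015, 0, 0]])
        centers = np.array([r.center for r in self.ROIS.rois[:3]]) + offsets * 0
        centers += [[0.015, 0, 0], [0, 0.015, 0], [0, 0, 0.015]]
        cs = _clusterset(centers, [6, 6, 6])
        tp_flags, fp = els.classify_clusters(cs, self.ROIS, 30.0)
        assert sum(tp_flags.values()) == 3
        assert fp.sum() == 0

    def test_equidistant_cluster_validates_both_rois(self):
        # one cluster 25 mm from two ROI centers: both become TPs
        net = _net_with_centers(
            [[0.025, 0, 0], [-0.025, 0, 0], [0, 0.08, 0], [0, -0.08, 0]]
        )
        cs = _clusterset([[0.0, 0.0, 0.0]], [6])
        tp_flags, fp = els.classify_clusters(cs, net, 30.0)
        assert tp_flags["roi0"] and tp_flags["roi1"]
        assert not tp_flags["roi2"] and not tp_flags["roi3"]
        assert fp.sum() == 0

    def test_distant_cluster_is_false_positive(self):
        cs = _clusterset([[0.0, 0.0, 0.2]], [6])
        tp_flags, fp = els.classify_clusters(cs, self.ROIS, 30.0)
        assert sum(tp_flags.values()) == 0
        assert fp.sum() == 1


class TestMetrics:
    def _run(self, cluster_centers, sizes, net=None, max_dist=30.0, roi_count=10):
        net = net or TestClassification.ROIS
        cs = _clusterset(cluster_centers, sizes)
        roi_sets = {r.name: np.arange(roi_count) for r in net.rois}
        src = _grid_sources()
        return els.compute_metrics(cs, net, roi_sets, src, max_dist)

    def test_three_tp_gives_sensitivity_075(self):
        centers = [r.center + [0.01, 0, 0] for r in TestClassification.ROIS.rois[:3]]
        res = self._run(centers, [6, 6, 6])
        assert res.tp == 3 and res.fn == 1
        assert res.sensitivity == 0.75

    def test_two_tp_gives_sensitivity_05(self):
        centers = [r.center + [0.01, 0, 0] for r in TestClassification.ROIS.rois[:2]]
        res = self._run(centers, [6, 6])
        assert res.sensitivity == 0.5

    def test_perfect_cluster_zero_error_zero_dispersion(self):
        net = TestClassification.ROIS
        res = self._run([net.rois[0].center], [10])  # same volume as the ROI
        assert res.per_roi_locerr_mm["roi0"] == 0.0
        assert res.per_roi_dispersion["roi0"] == 0.0

    def test_multiple_clusters_average_their_errors(self):
        net = TestClassification.ROIS
        c0 = net.rois[0].center
        res = self._run([c0 + [0.01, 0, 0], c0 + [-0.02, 0, 0]], [6, 6])
        assert res.per_roi_locerr_mm["roi0"] == pytest.approx(15.0)

    def test_precision_undefined_without_clusters(self):
        res = self._run(np.empty((0, 3)), [])
        assert res.tp == 0 and res.fn == 4 and res.fp == 0
        assert np.isnan(res.precision)
        assert np.isnan(res.localization_error_mm)

    def test_precision_mixes_roi_tp_and_cluster_fp(self):
        net = TestClassification.ROIS
        centers = [net.rois[0].center, [0.0, 0.0, 0.2]]  # 1 hit + 1 far FP
        res = self._run(centers, [6, 6])
        assert res.tp == 1 and res.fp == 1
        assert res.precision == 0.5


class TestEvaluatePipeline:
    def _fake_evoked(self, src, hot, amplitude=5.0, seed=0):
        rng = np.random.default_rng(seed)
        n, t = src.n_dipoles, 250
        noise = np.abs(rng.standard_normal((n, t))) * 0.01
        erp = noise + 0.0
        tax = -200.0 + np.arange(t) * 4.0
        win = (tax >= 100) & (tax <= 220)
        erp[np.ix_(hot, win)] += amplitude
        return _estimate(erp, cond="erp"), _estimate(noise, cond="noise")

    def test_recovers_planted_blob(self):
        src = _grid_sources()
        net = _net_with_centers(
            [[0.0, 0.0, 0.05], [0.03, 0.03, 0.05], [-0.03, 0.03, 0.05], [0.03, -0.03, 0.05]]
        )
        hot = els.select_roi_dipoles(src, net.rois[0])
        erp, noi = self._fake_evoked(src, hot)
        res = els.evaluate(erp, noi, net, src, EvalParams(max_dist_mm=10.0))
        assert res.roi_is_tp["roi0"]
        assert res.per_roi_locerr_mm["roi0"] < 5.0

    def test_deterministic(self):
        src = _grid_sources()
        net = _net_with_centers(
            [[0.0, 0.0, 0.05], [0.03, 0.03, 0.05], [-0.03, 0.03, 0.05], [0.03, -0.03, 0.05]]
        )
        hot = els.select_roi_dipoles(src, net.rois[0])
        erp, noi = self._fake_evoked(src, hot)
        r1 = els.evaluate(erp, noi, net, src)
        r2 = els.evaluate(erp, noi, net, src)
        assert (r1.tp, r1.fn, r1.fp, r1.sensitivity) == (r2.tp, r2.fn, r2.fp, r2.sensitivity)

    def test_tp_monotone_fp_antitone_in_max_dist(self):
        src = _grid_sources()
        net = _net_with_centers(
            [[0.0, 0.0, 0.05], [0.028, 0.028, 0.05], [-0.028, 0.028, 0.05], [0.028, -0.028, 0.05]]
        )
        hot = np.concatenate(
            [
                els.select_roi_dipoles(src, net.rois[0]),
                els.select_roi_dipoles(
                    src, els.ROISpec(name="x", center=[-0.022, -0.022, 0.05], radius_mm=8.0)
                ),
            ]
        )
        erp, noi = self._fake_evoked(src, hot)
        results = [
            els.evaluate(erp, noi, net, src, EvalParams(max_dist_mm=d))
            for d in (10.0, 30.0, 50.0)
        ]
        tps = [r.tp for r in results]
        fps = [r.fp for r in results]
        assert tps == sorted(tps)
        assert fps == sorted(fps, reverse=True)
        assert all(r.tp + r.fn == 4 for r in results)
        assert all(0.0 <= r.sensitivity <= 1.0 for r in results)
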