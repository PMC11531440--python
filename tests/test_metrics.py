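import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lcn.metrics as mx
import lcn.synth as synth
from lcn.datatypes import LCNGraph, SegmentedMask


def graph_with_edges(edges, nodes):
    g = LCNGraph()
    for nid, pos, kind in nodes:
        g.add_node(nid, pos, kind)
    for u, v, path in edges:
        g.add_edge(u, v, np.asarray(path, float))
    return g


class TestSubvolumeMaps:
    def test_edge_free_graph_zero_density(self):
        g = LCNGraph()
        g.add_node(0, [5, 5, 5], "junction")
        sm = mx.compute_subvolume_maps(g, (30, 30, 30))
        assert np.all(sm.can_dn[sm.valid] == 0.0)

    def test_single_spanning_canaliculus_exact_density(self):
        # one straight edge spanning cell (0,0,0) exactly edge to edge
        h = 400.0 ** (1.0 / 3.0)
        g = graph_with_edges(
            [(0, 1, [[0.0, h / 2, h / 2], [h, h / 2, h / 2]])],
            [(0, [0.0, h / 2, h / 2], "endpoint"), (1, [h, h / 2, h / 2], "endpoint")],
        )
        sm = mx.compute_subvolume_maps(g, (3 * h, 3 * h, 3 * h))
        assert sm.can_dn[0, 0, 0] == pytest.approx(h / 400.0, abs=1e-9)
        assert sm.can_dn[0, 0, 0] == pytest.approx(0.018420, abs=1e-5)

    def test_node_degree_cell_average(self):
        h = 400.0 ** (1.0 / 3.0)
        pts = {0: [1.0, 1, 1], 1: [2.0, 2, 2]}
        g = LCNGraph()
        g.add_node(0, pts[0], "junction")
        g.add_node(1, pts[1], "junction")
        far = 100
        nxt = 2
        # give node 0 degree 3 and node 1 degree 4 via distinct endpoints
        for nid, deg in ((0, 3), (1, 4)):
            for _ in range(deg):
                g.add_node(nxt, [far, 5.0, 5.0], "endpoint")
                g.add_edge(nid, nxt, np.array([pts[nid], [far, 5.0, 5.0]], float))
                far += 2
                nxt += 1
        sm = mx.compute_subvolume_maps(g, (3 * h, 3 * h, 3 * h))
        assert sm.nd_dg[0, 0, 0] == pytest.approx(3.5)
        assert sm.nd_nr[0, 0, 0] == pytest.approx(2 / 400.0)

    def test_length_conservation(self, small_truth):
        sm = mx.compute_subvolume_maps(small_truth.graph, (30, 30, 30))
        total = float(sm.can_dn.sum() * sm.v_sub_um3)
        truth = small_truth.graph.total_length_um()
        assert total == pytest.approx(truth, rel=1e-6)

    def test_roi_mask_invalidates_cells(self):
        g = LCNGraph()
        roi = np.ones((79, 79, 88), bool)
        roi[:40] = False
        sm = mx.compute_subvolume_maps(
            g, (30, 30, 30), roi_mask=roi, roi_spacing_um=(0.379, 0.379, 0.340)
        )
        assert not sm.valid[0, 0, 0]
        assert sm.valid[3, 0, 0]

    def test_empty_roi_warns(self):
        g = LCNGraph()
        roi = np.zeros((79, 79, 88), bool)
        sm = mx.compute_subvolume_maps(
            g, (30, 30, 30), roi_mask=roi, roi_spacing_um=(0.379, 0.379, 0.340)
        )
        assert sm.n_valid == 0
        assert sm.warnings


class TestLacunaMorphometry:
    @staticmethod
    def _voxelized_ellipsoid(a, b, c, spacing=(0.379, 0.379, 0.340)):
        spacing = np.asarray(spacing)
        half = np.array([a, b, c]) + 1.0
        shape = np.ceil(2 * half / spacing).astype(int)
        idx = np.indices(shape).reshape(3, -1).T
        pts = (idx + 0.5) * spacing - half
        inside = (
            (pts[:, 0] / a) ** 2 + (pts[:, 1] / b) ** 2 + (pts[:, 2] / c) ** 2
        ) <= 1.0
        labels = np.zeros(shape, dtype=np.int32)
        labels[tuple(idx[inside].T)] = 2  # lacuna id 1
        return SegmentedMask(labels, spacing)

    def test_ellipsoid_moments(self):
        seg = self._voxelized_ellipsoid(9.0, 5.0, 3.0)
        (shape,) = mx.lacuna_morphometry(seg)
        assert shape.volume_um3 == pytest.approx(565.5, rel=0.05)
        assert shape.stretch == pytest.approx(0.667, abs=0.02)
        assert shape.oblateness == pytest.approx(-0.333, abs=0.05)

    def test_sphere_degenerate_oblateness(self):
        seg = self._voxelized_ellipsoid(4.0, 4.0, 4.0)
        (shape,) = mx.lacuna_morphometry(seg)
        assert shape.stretch == pytest.approx(0.0, abs=0.02)
        # near-degenerate axes: oblateness is numerically unstable but bounded
        assert -1.0 <= shape.oblateness <= 1.0

    def test_tiny_lacuna_flagged(self):
        labels = np.zeros((10, 10, 10), np.int32)
        labels[5, 5, 5] = 2
        seg = SegmentedMask(labels, (0.379, 0.379, 0.340))
        (shape,) = mx.lacuna_morphometry(seg)
        assert not shape.valid
        assert math.isnan(shape.stretch)

    def test_generator_lacunae_in_reported_stretch_range(self):
        rng = np.random.default_rng(0)
        pop = synth.sample_lacuna_population(500, rng)
        stretches = np.array([l.stretch for l in pop])
        assert np.all((stretches >= 0.3) & (stretches <= 0.8))


class TestDegreeDistribution:
    def test_hand_computed_fit(self):
        fit = mx.cumulative_degree_fit(np.array([3, 3, 3, 4, 5]))
        assert fit.cumulative[0] == 1.0
        assert fit.cumulative[1] == pytest.approx(0.4)
        assert fit.cumulative[2] == pytest.approx(0.2)
        # beta = (1*ln(1/0.4) + 2*ln(1/0.2)) / (1 + 4)
        expected = (math.log(1 / 0.4) + 2 * math.log(1 / 0.2)) / 5.0
        assert fit.beta == pytest.approx(expected, abs=1e-12)
        assert fit.beta == pytest.approx(0.827, abs=0.001)

    def test_all_degree_three_undefined(self):
        fit = mx.cumulative_degree_fit(np.array([3, 3, 3, 3]))
        assert math.isnan(fit.beta)
        assert fit.note

    def test_recovery_at_1e5_samples(self):
        rng = np.random.default_rng(9)
        degs = synth._sample_degrees(rng, 100_000, 0.8)
        fit = mx.cumulative_degree_fit(degs)
        assert fit.beta == pytest.approx(0.8, abs=0.05)

    def test_no_genuine_nodes_raises(self):
        with pytest.raises(ValueError):
            mx.cumulative_degree_fit(np.array([1, 2]))

    @given(st.lists(st.integers(min_value=3, max_value=30), min_size=1, max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_cumulative_starts_at_one_and_decreases(self, degrees):
        fit = mx.cumulative_degree_fit(np.array(degrees))
        assert fit.cumulative[0] == 1.0
        assert np.all(np.diff(fit.cumulative) <= 1e-12)


class TestRegression:
    def test_exact_line(self):
        res = mx.linear_regression([0, 1, 2], [0, 2, 4])
        assert res.slope == pytest.approx(2.0, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_matches_closed_form(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        y = 1.3 * x + 0.7 + rng.normal(size=50)
        res = mx.linear_regression(x, y)
        # closed-form least squares
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        assert res.slope == pytest.approx(slope, abs=1e-10)
        assert res.intercept == pytest.approx(intercept, abs=1e-10)

    def test_power_law_exact(self):
        x = np.arange(1.0, 11.0)
        y = 2.0 * x**1.5
        res = mx.power_law_fit(x, y)
        assert abs(res.exponent - 1.5) < 1e-12
        assert abs(res.prefactor - 2.0) < 1e-12
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            mx.linear_regression([1, 1, 1], [0, 1, 2])

    def test_nonpositive_rejected_for_power_law(self):
        with pytest.raises(ValueError):
            mx.power_law_fit([0, 1, 2], [1, 2, 3])


class TestSmoothedHistogram:
    def test_normalization(self):
        rng = np.random.default_rng(0)
        h = mx.smoothed_histogram(rng.normal(size=500), np.linspace(-4, 4, 41))
        assert h.frequencies.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(h.frequencies >= 0)

    def test_sigma_zero_is_raw_histogram(self):
        vals = [0.5, 1.5, 1.5, 2.5]
        edges = [0, 1, 2, 3]
        h = mx.smoothed_histogram(vals, edges, sigma_bins=0.0)
        assert np.allclose(h.frequencies, [0.25, 0.5, 0.25])

    def test_single_bin_becomes_gaussian_bump(self):
        h = mx.smoothed_histogram([5.0] * 10, np.arange(0, 11), sigma_bins=1.0)
        peak = np.argmax(h.frequencies)
        assert h.bin_centers[peak] == pytest.approx(5.5)
        assert np.all(np.diff(h.frequencies[: peak + 1]) >= -1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mx.smoothed_histogram([], [0, 1, 2])


class TestVariability:
    def test_hand_example(self):
        summary = mx.variability_summary([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert summary.inter == pytest.approx(1.0)
        assert summary.intra == pytest.approx(1.0)

    def test_identical_samples_zero_inter(self):
        summary = mx.variability_summary([[1, 5, 9]] * 4)
        assert summary.inter == 0.0
        assert summary.intra > 0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            mx.variability_summary([[1, 2]])


class TestGroupComparison:
    def test_identical_groups(self):
        res = mx.group_comparison([1.0, 2, 3], [1.0, 2, 3], paired=True)
        assert res.t == 0.0
        assert res.p == 1.0

    def test_paired_closed_form(self):
        res = mx.group_comparison([1, 2, 3], [2, 2.5, 4.5], paired=True)
        assert abs(res.t) == pytest.approx(3.4641016, abs=1e-6)
        assert res.df == 2

    def test_independent_matches_closed_form(self):
        a = np.array([4.1, 5.2, 6.3, 5.5, 4.9])
        b = np.array([5.0, 6.1, 7.2, 6.6])
        res = mx.group_comparison(a, b)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
        assert res.t == pytest.approx(t, abs=1e-10)

    def test_paired_length_mismatch(self):
        with pytest.raises(ValueError):
            mx.group_comparison([1, 2], [1, 2, 3], paired=True)


class TestCohortStatistics:
    def test_inter_smaller_than_intra_for_can_dn(self):
        presets = [synth.STRAIN_PRESETS["balbc_like"]]
        base = synth.GeneratorParams(domain_size_um=(24, 24, 24))
        cohort = synth.generate_cohort(presets, 4, seed=2, base_params=base)
        per_sample = []
        for sample in cohort:
            sm = mx.compute_subvolume_maps(sample.truth.graph, (24, 24, 24))
            per_sample.append(sm.values("can_dn"))
        summary = mx.variability_summary(per_sample)
        assert summary.inter < summary.intra

    def test_beta_anticorrelates_with_mean_degree(self):
        rows = []
        for i, beta in enumerate(np.linspace(0.6, 2.5, 8)):
            rng = np.random.default_rng(100 + i)
            degs = synth._sample_degrees(rng, 20_000, beta)
            fit = mx.cumulative_degree_fit(degs)
            rows.append((fit.beta, degs.mean()))
        betas, means = zip(*rows)
        res = mx.linear_regression(betas, means)
        assert res.slope < 0
        assert res.r < -0.8
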