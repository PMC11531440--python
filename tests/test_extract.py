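import math

import numpy as np
import pytest

import lcn.extract as ex
import lcn.synth as synth
from lcn.datatypes import BinaryMask, ImageStack, LCNGraph, Skeleton

from conftest import make_empty_domain_params, make_manual_truth, straight_tube_graph

SPACING = (0.379, 0.379, 0.340)


def _tube_image(noise=False):
    p = make_empty_domain_params()
    g = straight_tube_graph(np.array([4.0, 6.0, 6.0]), np.array([16.0, 6.0, 6.0]))
    return synth.rasterize(make_manual_truth(p, g), p), p


class TestBinarize:
    def test_constant_stack_gives_empty_mask(self):
        stack = ImageStack(np.full((30, 30, 30), 3.5, np.float32), SPACING)
        assert ex.binarize_dog(stack).n_foreground == 0

    def test_clean_tube_dice(self):
        img, _ = _tube_image()
        mask = ex.binarize_dog(img)
        true = img.values > 0
        inter = (mask.mask & true).sum()
        dice = 2 * inter / (mask.n_foreground + true.sum())
        assert dice >= 0.7

    def test_background_gradient_robustness(self):
        # local adaptivity: a linear ramp must barely change the mask
        img, p = _tube_image()
        ramp_p = type(p)(**{**p.__dict__, "background_gradient": 0.02,
                            "psf_sigma_um": (0, 0, 0), "noise_sd": 0.0})
        ramped = synth.degrade(img, ramp_p)
        m0 = ex.binarize_dog(img)
        m1 = ex.binarize_dog(ramped)
        inter = (m0.mask & m1.mask).sum()
        dice = 2 * inter / (m0.n_foreground + m1.n_foreground)
        assert dice >= 0.95

    @pytest.mark.parametrize("k_pair", [(0.0, 0.5), (0.5, 1.5), (-0.5, 0.0)])
    def test_threshold_monotonicity(self, default_stack, k_pair):
        lo, hi = k_pair
        m_lo = ex.binarize_dog(default_stack, threshold_k=lo)
        m_hi = ex.binarize_dog(default_stack, threshold_k=hi)
        assert m_hi.n_foreground <= m_lo.n_foreground
        assert not np.any(m_hi.mask & ~m_lo.mask)

    def test_bad_sigmas_rejected(self, default_stack):
        with pytest.raises(ValueError):
            ex.binarize_dog(default_stack, sigma_small_um=1.2, sigma_large_um=0.3)


class TestSegmentLacunae:
    def test_thin_tube_is_all_canaliculus(self):
        img, _ = _tube_image()
        seg = ex.segment_lacunae(BinaryMask(img.values > 0, SPACING))
        assert len(seg.lacuna_ids) == 0
        assert seg.canaliculus_mask.sum() == (img.values > 0).sum()

    def test_empty_mask(self):
        seg = ex.segment_lacunae(BinaryMask(np.zeros((10, 10, 10), bool), SPACING))
        assert len(seg.lacuna_ids) == 0
        assert seg.canaliculus_mask.sum() == 0

    def test_ellipsoid_with_tubes_single_lacuna(self):
        from lcn.datatypes import LacunaShape
        from lcn.synth import TrueLacuna, ellipsoid_volume

        p = make_empty_domain_params(domain_size_um=(26.0, 16.0, 12.0))
        a, b, c = 9.0, 5.0, 3.0
        ctr = np.array([13.0, 8.0, 6.0])
        st, ob = LacunaShape.shape_descriptors(a, b, c)
        lac = TrueLacuna(
            shape=LacunaShape(1, ellipsoid_volume(a, b, c), (a, b, c), st, ob, 0,
                              centroid_um=ctr),
            centroid_um=ctr,
            rotation=np.eye(3),
        )
        g = LCNGraph()
        g.add_node(0, ctr, "lacuna", lacuna_id=1)
        g.add_node(1, [24.0, 8.0, 6.0], "endpoint")
        g.add_edge(0, 1, np.array([[22.05, 8.0, 6.0], [24.0, 8.0, 6.0]]))
        img = synth.rasterize(make_manual_truth(p, g, [lac]), p)
        seg = ex.segment_lacunae(BinaryMask(img.values > 0.5, SPACING))
        assert list(seg.lacuna_ids) == [1]
        vol = seg.lacuna_mask(1).sum() * seg.voxel_volume_um3
        assert vol == pytest.approx(565.5, rel=0.10)


class TestSkeleton:
    def test_straight_cylinder_single_path(self):
        img, _ = _tube_image()
        seg = ex.segment_lacunae(BinaryMask(img.values > 0, SPACING))
        skel = ex.skeletonize_mask(seg)
        branches, centroids = ex.smooth_branches(skel)
        assert len(branches) == 1
        bp = branches[0]
        assert bp.end_a[0] == "endpoint" and bp.end_b[0] == "endpoint"
        # centerline within one voxel diagonal of the analytic axis
        d_axis = np.linalg.norm(bp.points_um[:, 1:] - np.array([6.0, 6.0]), axis=1)
        assert d_axis.max() <= np.linalg.norm(SPACING)

    def test_y_tube_one_junction_three_branches(self):
        p = make_empty_domain_params(domain_size_um=(20.0, 20.0, 12.0))
        g = LCNGraph()
        ctr = np.array([10.0, 10.0, 6.0])
        g.add_node(0, ctr, "junction")
        dirs = [np.array([1.0, 0, 0]), np.array([-0.5, 0.8, 0]), np.array([-0.5, -0.8, 0])]
        for i, d in enumerate(dirs):
            end = ctr + 6.0 * d / np.linalg.norm(d)
            g.add_node(i + 1, end, "endpoint")
            g.add_edge(0, i + 1, np.vstack([ctr, end]))
        img = synth.rasterize(make_manual_truth(p, g), p)
        seg = ex.segment_lacunae(BinaryMask(img.values > 0, SPACING))
        skel = ex.skeletonize_mask(seg)
        branches, centroids = ex.smooth_branches(skel)
        assert len(centroids) == 1
        assert len(branches) == 3
        graph = ex.build_graph(branches, seg, centroids)
        junctions = graph.nodes_of_kind("junction")
        assert len(junctions) == 1
        assert graph.degree(junctions[0]) == 3
        assert len(graph.nodes_of_kind("endpoint")) == 3
        assert graph.n_edges == 3

    def test_empty_segmentation_empty_skeleton(self):
        seg = ex.segment_lacunae(BinaryMask(np.zeros((10, 10, 10), bool), SPACING))
        skel = ex.skeletonize_mask(seg)
        assert skel.n_voxels == 0
        branches, centroids = ex.smooth_branches(skel)
        assert branches == [] and centroids == {}


class TestSmoothing:
    def test_collinear_path_keeps_length(self):
        spacing = np.array(SPACING)
        n = int(round(10.0 / 0.379)) + 1
        pts = np.column_stack(
            [np.linspace(0, 10.0, n), np.zeros(n), np.zeros(n)]
        )
        out = ex._smooth_path_um(pts, spacing)
        arc = np.linalg.norm(np.diff(out, axis=0), axis=1).sum()
        assert arc == pytest.approx(10.0, abs=1e-6)

    def test_staircase_shrinks_toward_chord(self):
        spacing = np.array(SPACING)
        # alternating x/y steps: a 45° line discretized on the voxel grid
        steps = []
        pos = np.zeros(3)
        for i in range(30):
            pos = pos + (np.array([0.379, 0, 0]) if i % 2 == 0 else np.array([0, 0.379, 0]))
            steps.append(pos.copy())
        pts = np.vstack([np.zeros(3)] + steps)
        poly = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        chord = np.linalg.norm(pts[-1] - pts[0])
        out = ex._smooth_path_um(pts, spacing)
        arc = np.linalg.norm(np.diff(out, axis=0), axis=1).sum()
        assert chord <= arc < poly

    def test_three_point_path_unsmoothed(self):
        spacing = np.array(SPACING)
        pts = np.array([[0.0, 0, 0], [0.4, 0.1, 0], [0.8, 0, 0]])
        out = ex._smooth_path_um(pts, spacing)
        assert np.array_equal(out, pts)


class TestBuildGraph:
    def test_isolated_lacuna_degree_zero(self):
        from lcn.datatypes import LacunaShape
        from lcn.synth import TrueLacuna, ellipsoid_volume

        p = make_empty_domain_params(domain_size_um=(16.0, 14.0, 12.0))
        ctr = np.array([8.0, 7.0, 6.0])
        st, ob = LacunaShape.shape_descriptors(5.0, 4.0, 3.0)
        lac = TrueLacuna(
            shape=LacunaShape(1, ellipsoid_volume(5, 4, 3), (5, 4, 3), st, ob, 0,
                              centroid_um=ctr),
            centroid_um=ctr,
            rotation=np.eye(3),
        )
        img = synth.rasterize(make_manual_truth(p, LCNGraph(), [lac]), p)
        seg = ex.segment_lacunae(BinaryMask(img.values > 0.5, SPACING))
        skel = ex.skeletonize_mask(seg)
        branches, centroids = ex.smooth_branches(skel)
        graph = ex.build_graph(branches, seg, centroids)
        assert len(graph.nodes_of_kind("lacuna")) == 1
        assert graph.n_edges == 0
        assert graph.lacuna_degrees() == {1: 0}

    def test_degree_sum_equals_twice_edges(self, default_extraction):
        g = default_extraction.graph
        total_degree = sum(g.degree(n) for n in g.g.nodes)
        assert total_degree == 2 * g.n_edges

    def test_junctions_have_degree_three_after_pruning(self, default_extraction):
        g = default_extraction.graph
        for n in g.nodes_of_kind("junction"):
            assert g.degree(n) >= 3


class TestRecovery:
    """End-to-end extraction on the default noisy phantom vs ground truth."""

    def test_total_length_within_15pct(self, default_truth, default_extraction):
        true_len = default_truth.graph.total_length_um()
        got = default_extraction.graph.total_length_um()
        assert got == pytest.approx(true_len, rel=0.15)

    def test_junction_count_within_20pct(self, default_truth, default_extraction):
        true_j = default_truth.realized["n_junctions"]
        got = len(default_extraction.graph.genuine_nodes())
        assert got == pytest.approx(true_j, rel=0.20)

    def test_mean_degree_within_0p3(self, default_truth, default_extraction):
        got = default_extraction.graph.genuine_degrees().mean()
        assert abs(got - default_truth.realized["nd_dg"]) <= 0.3

    def test_lacuna_count_exact(self, default_truth, default_extraction):
        assert len(default_extraction.segmentation.lacuna_ids) == int(
            default_truth.realized["n_lacunae"]
        )

    def test_lacuna_degree_within_20pct_on_average(
        self, default_truth, default_extraction
    ):
        import lcn.metrics as mx

        shapes = mx.lacuna_morphometry(
            default_extraction.segmentation, default_extraction.graph
        )
        errs = []
        for sh in shapes:
            best = min(
                default_truth.lacunae,
                key=lambda l: np.linalg.norm(l.centroid_um - sh.centroid_um),
            )
            errs.append(abs(sh.degree - best.shape.degree) / best.shape.degree)
        assert np.mean(errs) <= 0.20

    def test_pipeline_determinism(self, default_stack):
        r1 = ex.extract_network(default_stack)
        r2 = ex.extract_network(default_stack)
        assert r1.graph.n_nodes == r2.graph.n_nodes
        assert r1.graph.n_edges == r2.graph.n_edges
        assert r1.graph.total_length_um() == r2.graph.total_length_um()
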