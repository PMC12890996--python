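"""Mitochondrial morphometry: segmentation, particle and skeleton features."""

import numpy as np
import pytest

from cmquant import mito as mt
from cmquant import skeleton_reference as ref
from cmquant.synthetic import MitoImageSpec, gen_mito_image

FIXED = mt.SegConfig(smoothing_sigma=0, threshold_method="fixed", fixed_threshold=5,
                     min_object_px=1)


def _graph_summary(skel):
    f = mt.skeleton_features(mt.skeleton_graph(skel))
    return (f.n_branches, tuple(f.branch_lengths), tuple(f.node_degrees),
            f.avg_node_degree)


class TestSegmentMito:
    def test_blank_image(self):
        mask = mt.segment_mito(np.zeros((16, 16)), FIXED)
        assert mask.n_labels == 0

    def test_two_squares_fixed_threshold(self):
        img = np.zeros((24, 24))
        img[2:12, 2:12] = 10.0
        img[14:24, 14:24] = 10.0
        mask = mt.segment_mito(img, FIXED)
        feats = mt.particle_features(mask)
        assert feats.count == 2
        assert sorted(feats.areas) == [100.0, 100.0]

    def test_uniform_image_otsu_warns_zero_particles(self):
        with pytest.warns(UserWarning, match="uniform"):
            mask = mt.segment_mito(np.full((16, 16), 3.0),
                                   mt.SegConfig(threshold_method="otsu"))
        assert mask.n_labels == 0

    def test_min_object_px_removes_specks(self):
        img = np.zeros((20, 20))
        img[2, 2] = 10.0  # single-pixel speck
        img[5:15, 5:15] = 10.0
        cfg = mt.SegConfig(smoothing_sigma=0, threshold_method="fixed",
                           fixed_threshold=5, min_object_px=4)
        assert mt.segment_mito(img, cfg).n_labels == 1

    def test_generator_fixture_count_matches_truth(self):
        spec = MitoImageSpec(primitives=[("rect", 2, 2, 8, 8), ("line", 20, 4, 20, 30),
                                         ("rect", 30, 30, 40, 34)])
        img, truth = gen_mito_image(spec)
        mask = mt.segment_mito(img, mt.SegConfig(smoothing_sigma=0,
                                                 threshold_method="fixed",
                                                 fixed_threshold=500, min_object_px=1))
        assert mask.n_labels == truth.particles.count


class TestParticleFeatures:
    def test_square_is_convex(self):
        img = np.zeros((20, 20))
        img[5:15, 5:15] = 10.0
        feats = mt.particle_features(mt.segment_mito(img, FIXED))
        assert feats.areas[0] == 100.0
        assert feats.solidity[0] == pytest.approx(1.0, abs=1e-12)
        assert feats.perimeters[0] == pytest.approx(36.0)

    def test_l_shape_solidity_fixed_by_hull_convention(self, l_shape_image):
        feats = mt.particle_features(mt.segment_mito(l_shape_image, FIXED))
        assert feats.areas[0] == 75.0
        # hull over pixel centers spans 85 lattice points (hand-checkable)
        assert feats.solidity[0] == pytest.approx(75.0 / 85.0, abs=1e-12)

    def test_matches_reference_route(self, l_shape_image):
        mask = mt.segment_mito(l_shape_image, FIXED)
        feats = mt.particle_features(mask)
        pixels = mask.pixel_sets()[0]
        assert feats.solidity[0] == pytest.approx(ref.solidity_reference(pixels),
                                                  abs=1e-12)
        assert feats.perimeters[0] == pytest.approx(ref.perimeter_reference(pixels),
                                                    abs=1e-9)

    def test_empty_mask(self):
        feats = mt.particle_features(mt.LabeledMask(np.zeros((8, 8), int), 0))
        assert feats.count == 0
        assert feats.areas.size == 0

    def test_thin_line_solidity_one(self):
        img = np.zeros((12, 12))
        img[4, 2:10] = 10.0
        feats = mt.particle_features(mt.segment_mito(img, FIXED))
        assert feats.solidity[0] == pytest.approx(1.0)
        assert feats.perimeters[0] == pytest.approx(14.0)  # 7 out + 7 back


class TestSkeletonize:
    def test_idempotent_on_battery(self, shape_battery):
        for name, shape in shape_battery:
            sk = mt.skeletonize_mask(shape)
            again = mt.skeletonize_mask(sk)
            assert np.array_equal(sk, again), name

    def test_skeleton_not_larger_than_mask(self):
        img = np.zeros((20, 40), bool)
        img[5:10, 5:35] = True
        sk = mt.skeletonize_mask(img)
        assert sk.sum() <= img.sum()

    def test_bar_skeleton_is_single_path(self):
        img = np.zeros((9, 21), bool)
        img[3:6, 3:18] = True  # filled 3x15 bar
        f = mt.skeleton_features(mt.skeleton_graph(mt.skeletonize_mask(img)))
        assert f.n_branches == 1
        assert tuple(f.node_degrees) == (1, 1)

    def test_empty_mask(self):
        assert not mt.skeletonize_mask(np.zeros((5, 5), bool)).any()


class TestSkeletonGraph:
    def test_straight_line(self):
        sk = np.zeros((20, 20), bool)
        sk[5, 3:13] = True
        n, lengths, degrees, avg = _graph_summary(sk)
        assert n == 1
        assert lengths == (9.0,)
        assert degrees == (1, 1)
        assert avg == 1.0

    def test_plus_cross(self):
        sk = np.zeros((24, 24), bool)
        sk[12, 8:17] = True
        sk[8:17, 12] = True
        n, lengths, degrees, avg = _graph_summary(sk)
        assert n == 4
        assert degrees == (1, 1, 1, 1, 4)
        assert avg == pytest.approx(1.6)

    def test_isolated_cycle_single_self_branch(self):
        sk = np.zeros((32, 32), bool)
        r0, c0, rad = 16, 16, 6
        for dr in range(-rad, rad + 1):
            dc = rad - abs(dr)
            sk[r0 + dr, c0 + dc] = True
            sk[r0 + dr, c0 - dc] = True
        n, lengths, degrees, avg = _graph_summary(sk)
        assert n == 1
        assert degrees == (2,)
        assert lengths[0] == pytest.approx(24 * np.sqrt(2))

    def test_empty_skeleton(self):
        assert _graph_summary(np.zeros((6, 6), bool)) == (0, (), (), 0.0)

    def test_matches_reference_on_battery(self, shape_battery):
        for name, shape in shape_battery:
            mine = _graph_summary(shape)
            s = ref.summarize_skeleton_reference(shape)
            theirs = (s.n_branches, s.branch_lengths, s.node_degrees,
                      s.avg_node_degree)
            assert mine[0] == theirs[0], name
            assert np.allclose(mine[1], theirs[1], atol=1e-9), name
            assert mine[2] == theirs[2], name
            assert mine[3] == pytest.approx(theirs[3], abs=1e-12), name


class TestInvariances:
    def test_rotation_90_particle_features(self, l_shape_image):
        base = mt.particle_features(mt.segment_mito(l_shape_image, FIXED))
        rot = mt.particle_features(mt.segment_mito(np.rot90(l_shape_image), FIXED))
        assert base.count == rot.count
        assert np.allclose(sorted(base.areas), sorted(rot.areas))
        assert np.allclose(sorted(base.perimeters), sorted(rot.perimeters))
        assert np.allclose(sorted(base.solidity), sorted(rot.solidity))

    def test_rotation_90_skeleton_features(self, shape_battery):
        for name, shape in dict(shape_battery).items():
            if name not in ("plus_cross", "t_shape", "comb", "diamond_loop"):
                continue
            a = _graph_summary(shape)
            b = _graph_summary(np.rot90(shape))
            assert a[0] == b[0] and a[2] == b[2], name
            assert np.allclose(a[1], b[1]), name

    def test_translation_invariance(self):
        img = np.zeros((30, 30))
        img[2:9, 2:12] = 10.0
        shifted = np.roll(np.roll(img, 7, axis=0), 9, axis=1)
        a = mt.particle_features(mt.segment_mito(img, FIXED))
        b = mt.particle_features(mt.segment_mito(shifted, FIXED))
        assert a.areas.tolist() == b.areas.tolist()
        assert a.perimeters.tolist() == b.perimeters.tolist()
        assert a.solidity.tolist() == b.solidity.tolist()


class TestPerCellSummary:
    def test_blank_cell_all_zero(self):
        rec = mt.per_cell_summary(np.zeros((16, 16)), FIXED)
        assert rec["count"] == 0
        assert rec["total_area_px"] == 0.0
        assert rec["avg_node_degree"] == 0.0

    def test_single_square_cell(self):
        img = np.zeros((20, 20))
        img[5:15, 5:15] = 10.0
        rec = mt.per_cell_summary(img, FIXED)
        assert rec["count"] == 1
        skel = mt.skeletonize_mask(mt.segment_mito(img, FIXED))
        expected = mt.skeleton_features(mt.skeleton_graph(skel)).avg_node_degree
        assert rec["avg_node_degree"] == pytest.approx(expected)

    def test_cohort_sizes_match_study_design(self):
        # 38 control + 36 treated cells -> 74 records
        rng = np.random.default_rng(0)
        records = []
        for group, n_cells in (("control", 38), ("light", 36)):
            for i in range(n_cells):
                img = np.zeros((24, 24))
                r, c = rng.integers(2, 12, 2)
                img[r : r + 8, c : c + 8] = 10.0
                records.append(mt.per_cell_summary(img, FIXED, cell_id=f"{group}{i}",
                                                   group=group))
        assert len(records) == 74
        assert sum(r["group"] == "control" for r in records) == 38

    def test_micron_scaling_applies_to_lengths_and_areas(self):
        img = np.zeros((20, 20))
        img[5:15, 5:15] = 10.0
        px = mt.per_cell_summary(img, FIXED)
        cfg = mt.SegConfig(smoothing_sigma=0, threshold_method="fixed",
                           fixed_threshold=5, min_object_px=1, um_per_px=0.5)
        um = mt.per_cell_summary(img, cfg)
        assert um["total_area_px"] == pytest.approx(px["total_area_px"] * 0.25)
        assert um["mean_perimeter_px"] == pytest.approx(px["mean_perimeter_px"] * 0.5)
        assert um["count"] == px["count"]
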