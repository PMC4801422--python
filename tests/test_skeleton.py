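import math

import numpy as np
import pytest
from scipy import ndimage as ndi

import oracles
from conftest import raster_y
from nmjmorph import skeleton as sk
from nmjmorph.io_stack import Calibration
from nmjmorph.roi import RoiMask
from nmjmorph.skeleton import (
    build_skeleton_graph,
    segment_for_skeleton,
    skeleton_features,
    skeletonize,
)


class TestSegmentForSkeleton:
    @pytest.mark.parametrize(
        "marker,selector_name",
        [("dlg1", "li_threshold"), ("syt", "li_threshold"), ("csp", "li_threshold"),
         ("hrp", "renyi_entropy_threshold")],
    )
    def test_selector_dispatch(self, marker, selector_name, monkeypatch):
        called = []

        def spy(hist, _name=selector_name):
            called.append(_name)
            return 128

        monkeypatch.setitem(sk._MARKER_SELECTOR, marker, spy)
        img = np.zeros((60, 60))
        img[20:40, 20:40] = 500.0
        segment_for_skeleton(img, RoiMask(np.ones((60, 60), bool)), marker)
        assert called == [selector_name]

    def test_unknown_marker(self):
        with pytest.raises(ValueError):
            segment_for_skeleton(np.zeros((5, 5)), RoiMask(np.ones((5, 5), bool)), "gfp")

    def test_blank_roi_flagged(self):
        mask, empty = segment_for_skeleton(
            np.zeros((40, 40)), RoiMask(np.ones((40, 40), bool)), "dlg1"
        )
        assert empty and not mask.any()


class TestSkeletonize:
    def test_wide_bar_thins_to_line(self):
        m = np.zeros((9, 40), bool)
        m[3:6, 5:35] = True
        s = skeletonize(m)
        assert s.sum() <= 30 and s.any()
        assert (s.sum(axis=0) <= 1).all()  # one pixel thick

    def test_disc_collapses_to_point(self):
        yy, xx = np.mgrid[0:40, 0:40]
        m = (yy - 20) ** 2 + (xx - 20) ** 2 <= 144
        assert skeletonize(m).sum() <= 4

    def test_component_count_preserved(self):
        m = np.zeros((20, 40), bool)
        m[4:7, 5:35] = True
        m[14:17, 5:35] = True
        s = skeletonize(m)
        assert ndi.label(s, np.ones((3, 3)))[1] == 2

    def test_empty_in_empty_out(self):
        assert not skeletonize(np.zeros((5, 5), bool)).any()

    def test_subset_of_input(self):
        rng = np.random.default_rng(0)
        m = ndi.binary_dilation(rng.random((30, 30)) > 0.9, iterations=2)
        s = skeletonize(m)
        assert not (s & ~m).any()


class TestBuildGraph:
    def test_straight_line(self, cal_widefield):
        m = np.zeros((10, 80), bool)
        m[5, 5:75] = True
        f = skeleton_features(build_skeleton_graph(m, cal_widefield, spur_prune_um=0))
        assert f.n_branches == 1 and f.n_branching_points == 0 and f.n_islands == 1
        assert f.total_length_um == pytest.approx(69 / 6.932, rel=1e-6)

    def test_y_topology(self, cal_unit):
        s = skeletonize(raster_y())
        f = skeleton_features(build_skeleton_graph(s, cal_unit, spur_prune_um=0))
        assert (f.n_islands, f.n_branches, f.n_branching_points) == (1, 3, 1)

    def test_spur_pruned_and_reclassified(self, cal_unit):
        m = np.zeros((20, 60), bool)
        m[10, 5:55] = True
        m[9, 30] = m[8, 31] = m[7, 32] = True  # 3-px diagonal spur
        f = skeleton_features(build_skeleton_graph(m, cal_unit, spur_prune_um=5.0))
        assert (f.n_branches, f.n_branching_points) == (1, 0)
        assert f.total_length_um == pytest.approx(49.0)

    def test_empty_graph(self, cal_unit):
        f = skeleton_features(build_skeleton_graph(np.zeros((5, 5), bool), cal_unit))
        assert f.total_length_um == 0 and "empty_skeleton" in f.flags


class TestFeatures:
    def test_single_path(self, cal_unit):
        m = np.zeros((5, 12), bool)
        m[2, 1:12] = True
        f = skeleton_features(build_skeleton_graph(m, cal_unit, spur_prune_um=0))
        assert (
            f.total_length_um,
            f.longest_branch_length_um,
            f.n_islands,
            f.n_branches,
            f.n_branching_points,
        ) == (10.0, 10.0, 1, 1, 0)

    def test_y_longest_is_two_longest_arms(self, cal_unit):
        s = skeletonize(raster_y(length=30))
        f = skeleton_features(build_skeleton_graph(s, cal_unit, spur_prune_um=0))
        assert f.longest_branch_length_um < f.total_length_um
        assert f.longest_branch_length_um >= f.total_length_um * 2 / 3 - 2

    def test_extra_island_adds_length_and_component(self, cal_unit):
        s = skeletonize(raster_y())
        f0 = skeleton_features(build_skeleton_graph(s, cal_unit, spur_prune_um=0))
        s2 = s.copy()
        s2[75, 10:30] = True  # separate 20-px segment
        f1 = skeleton_features(build_skeleton_graph(s2, cal_unit, spur_prune_um=0))
        assert f1.n_islands == f0.n_islands + 1
        assert f1.n_branches == f0.n_branches + 1
        assert f1.total_length_um == pytest.approx(f0.total_length_um + 19.0)
        assert f1.longest_branch_length_um == f0.longest_branch_length_um

    def test_longest_matches_bruteforce_enumeration(self, cal_unit):
        fixtures = []
        s = skeletonize(raster_y())
        s[75, 10:40] = True
        fixtures.append(s)
        # cyclic fixture: ring with a tail
        yy, xx = np.mgrid[0:50, 0:50]
        r2 = (yy - 25) ** 2 + (xx - 25) ** 2
        ring = (r2 <= 15**2) & (r2 >= 12**2)
        ring[25, 40:48] = True
        fixtures.append(skeletonize(ring))
        for m in fixtures:
            g = build_skeleton_graph(m, cal_unit, spur_prune_um=0)
            f = skeleton_features(g)
            assert f.longest_branch_length_um == pytest.approx(
                oracles.longest_endpoint_path(g.graph), rel=1e-9
            )

    def test_invariant_under_translation_and_rotation(self, cal_unit):
        base = skeletonize(raster_y(shape=(100, 100), center=(45, 45)))
        f0 = skeleton_features(build_skeleton_graph(base, cal_unit))

        shifted = np.roll(np.roll(base, 7, axis=0), -5, axis=1)
        f1 = skeleton_features(build_skeleton_graph(shifted, cal_unit))
        rotated = np.rot90(base)
        f2 = skeleton_features(build_skeleton_graph(rotated, cal_unit))
        for f in (f1, f2):
            assert (f.n_islands, f.n_branches, f.n_branching_points) == (
                f0.n_islands,
                f0.n_branches,
                f0.n_branching_points,
            )
            assert f.total_length_um == pytest.approx(f0.total_length_um, rel=1e-9)
            assert f.longest_branch_length_um == pytest.approx(
                f0.longest_branch_length_um, rel=1e-9
            )

    def test_invariants_hold_on_random_trees(self, cal_unit):
        from nmjmorph.synthgen import _disk, _seg_points, random_tree

        for i in range(5):
            rng = np.random.default_rng(300 + i)
            tree = random_tree(rng, 5, (300, 300), margin=15, arm_len=(20, 60), clearance=8)
            m = np.zeros((300, 300), bool)
            for p0, p1 in tree.segments:
                for y, x in _seg_points(p0, p1, step=0.5):
                    m[int(round(y)), int(round(x))] = True
            m = ndi.binary_dilation(m, structure=_disk(1))
            f = skeleton_features(build_skeleton_graph(skeletonize(m), cal_unit))
            assert f.longest_branch_length_um <= f.total_length_um
            assert f.n_branching_points <= f.n_branches
            assert (f.n_islands, f.n_branches, f.n_branching_points) == (
                1,
                tree.n_branches,
                tree.n_branching_points,
            )
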