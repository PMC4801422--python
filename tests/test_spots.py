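import numpy as np
import pytest
from scipy import ndimage as ndi

import oracles
from nmjmorph.spots import (
    AUTO_HUANG,
    SpotParams,
    count_active_zones,
    find_maxima_3d,
    grey_close_3d,
)


def gaussian_spots(shape, centers, amplitude=1000.0, sigma=2.0, sigma_z=1.0):
    zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    stack = np.zeros(shape)
    for z, y, x in centers:
        stack += amplitude * np.exp(
            -0.5 * (((zz - z) / sigma_z) ** 2 + ((yy - y) / sigma) ** 2 + ((xx - x) / sigma) ** 2)
        )
    return stack


FIVE = [(10, 10, 10), (10, 10, 40), (10, 40, 10), (10, 40, 40), (10, 25, 25)]


class TestGreyClose:
    def test_radius_zero_identity(self):
        rng = np.random.default_rng(0)
        stack = rng.integers(0, 100, size=(4, 6, 6)).astype(float)
        np.testing.assert_array_equal(grey_close_3d(stack, 0), stack)

    def test_dark_voxel_in_plateau_filled(self):
        stack = np.full((5, 7, 7), 100.0)
        stack[2, 3, 3] = 10.0
        out = grey_close_3d(stack, 1)
        assert out[2, 3, 3] == 100.0

    def test_output_bounds_input(self):
        rng = np.random.default_rng(1)
        stack = rng.uniform(0, 50, size=(5, 8, 8))
        assert (grey_close_3d(stack, 1) >= stack - 1e-12).all()

    def test_matches_dilate_erode_oracle(self):
        rng = np.random.default_rng(2)
        stack = rng.uniform(0, 100, size=(4, 6, 5))
        from skimage.morphology import ball

        fp = ball(1)
        oracle = oracles.grey_dilate_then_erode(stack, fp)
        np.testing.assert_allclose(grey_close_3d(stack, 1), oracle)


class TestFindMaxima:
    def test_five_isolated_spots(self):
        stack = gaussian_spots((20, 64, 64), FIVE)
        foot = np.ones((64, 64), bool)
        s = find_maxima_3d(stack, SpotParams(noise_tolerance=100, min_intensity=250), foot)
        assert s.count == 5
        found = {(round(y), round(x)) for _, y, x in s.coordinates}
        assert found == {(y, x) for _, y, x in FIVE}

    def test_spots_are_26_neighborhood_maxima(self):
        """Every reported spot is a genuine 26-neighborhood maximum."""
        stack = gaussian_spots((16, 40, 40), [(8, 10, 10), (8, 28, 30)])
        maxima = oracles.local_maxima_26(stack)
        s = find_maxima_3d(
            stack, SpotParams(noise_tolerance=50, min_intensity=250), np.ones((40, 40), bool)
        )
        for z, y, x in s.coordinates:
            assert maxima[round(z), round(y), round(x)]

    def test_plateau_collapses_to_one_spot(self):
        stack = np.zeros((7, 9, 9))
        stack[3, 4:6, 4:6] = 1000.0  # 4 mutually adjacent maximal voxels
        s = find_maxima_3d(stack, SpotParams(noise_tolerance=10, min_intensity=250),
                           np.ones((9, 9), bool))
        assert s.count == 1

    def test_floor_excludes_dim_spot(self):
        stack = np.zeros((7, 9, 9))
        stack[3, 4, 4] = 200.0
        s = find_maxima_3d(stack, SpotParams(noise_tolerance=10, min_intensity=250),
                           np.ones((9, 9), bool))
        assert s.count == 0

    def test_footprint_excludes_outside_spots(self):
        stack = gaussian_spots((12, 40, 40), [(6, 10, 10), (6, 30, 30)])
        foot = np.zeros((40, 40), bool)
        foot[:20, :20] = True  # only the first spot inside
        s = find_maxima_3d(stack, SpotParams(noise_tolerance=50, min_intensity=250), foot)
        assert s.count == 1

    def test_empty_footprint_errors(self):
        with pytest.raises(ValueError):
            find_maxima_3d(np.zeros((3, 4, 4)), SpotParams(), np.zeros((4, 4), bool))

    def test_monotone_in_tolerance_and_floor(self):
        rng = np.random.default_rng(5)
        stack = gaussian_spots((16, 48, 48), [(8, 12, 12), (8, 12, 36), (8, 36, 24)])
        stack += rng.normal(50, 20, stack.shape).clip(0)
        foot = np.ones((48, 48), bool)
        counts_tol = [
            find_maxima_3d(stack, SpotParams(noise_tolerance=t, min_intensity=100), foot).count
            for t in (20, 60, 150, 400, 1200)
        ]
        assert counts_tol == sorted(counts_tol, reverse=True)
        counts_floor = [
            find_maxima_3d(stack, SpotParams(noise_tolerance=60, min_intensity=f), foot).count
            for f in (50, 150, 400, 900, 1500)
        ]
        assert counts_floor == sorted(counts_floor, reverse=True)

    def test_robust_to_subtolerance_noise(self):
        centers = [(8, 8 + 10 * i, 8 + 7 * j) for i in range(4) for j in range(5)]
        clean = gaussian_spots((16, 56, 48), centers)
        foot = np.ones((56, 48), bool)
        params = SpotParams(noise_tolerance=200, min_intensity=400)
        base = find_maxima_3d(grey_close_3d(clean, 1), params, foot).count
        rng = np.random.default_rng(9)
        noisy = clean + rng.uniform(-90, 90, clean.shape)  # amplitude < tolerance/2
        pert = find_maxima_3d(grey_close_3d(noisy, 1), params, foot).count
        assert abs(pert - base) <= max(1, round(0.02 * base))

    def test_auto_huang_floor_separates_background(self):
        rng = np.random.default_rng(3)
        stack = gaussian_spots((16, 48, 48), [(8, 12, 12), (8, 30, 30)])
        stack += rng.normal(60, 10, stack.shape).clip(0)
        foot = np.ones((48, 48), bool)
        s = find_maxima_3d(stack, SpotParams(noise_tolerance=150, min_intensity=AUTO_HUANG), foot)
        assert s.count == 2


class TestCountActiveZones:
    def test_spots_outside_outline_not_counted(self):
        from nmjmorph.io_stack import NmjStackPair
        from nmjmorph.outline import OutlineMask
        from nmjmorph.roi import RoiMask

        stack = gaussian_spots((10, 40, 40), [(5, 30, 30)])
        marker = np.zeros_like(stack)
        pair = NmjStackPair("t", marker.astype(np.uint16), stack.astype(np.uint16))
        outline = np.zeros((40, 40), bool)
        outline[5:15, 5:15] = True  # spot lies outside
        s = count_active_zones(
            pair,
            OutlineMask(outline),
            RoiMask(np.ones((40, 40), bool)),
            SpotParams(noise_tolerance=50, min_intensity=250),
        )
        assert s.count == 0


def test_confocal_preset_values():
    p = SpotParams.confocal()
    assert p.noise_tolerance == 100 and p.min_intensity == 250
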