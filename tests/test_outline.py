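import numpy as np
import pytest
from scipy import ndimage as ndi

from conftest import disc_chain, disc_mask
from nmjmorph.io_stack import Calibration
from nmjmorph.outline import (
    OutlineMask,
    count_boutons_watershed,
    measure_area,
    measure_perimeter,
    remove_small_particles,
    segment_outline,
    subtract_background,
)
from nmjmorph.roi import RoiMask


def _ball_profile(radius):
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    d2 = yy**2 + xx**2
    prof = np.full(yy.shape, -np.inf)
    inside = d2 <= radius**2
    prof[inside] = np.sqrt(radius**2 - d2[inside]) - radius
    return prof


class TestSubtractBackground:
    def test_constant_image_zeroed(self):
        img = np.full((50, 50), 37.0)
        assert np.allclose(subtract_background(img, 20), 0.0)

    def test_small_spot_preserved(self):
        a = 100.0
        img = np.full((80, 80), 10.0)
        img[40:43, 40:43] += a
        out = subtract_background(img, 20)
        assert abs(out[41, 41] - a) <= 0.1 * a
        far = out[:20, :20]
        assert far.max() < 0.05 * a

    def test_spots_on_gentle_ramp(self):
        a = 100.0
        yy, xx = np.mgrid[0:100, 0:100]
        img = 10.0 + 0.2 * (yy + xx)  # slope << a / radius
        peaks = [(25, 25), (70, 60)]
        for y, x in peaks:
            img[y - 1 : y + 2, x - 1 : x + 2] += a
        out = subtract_background(img, 20)
        for y, x in peaks:
            assert abs(out[y, x] - a) <= 0.1 * a

    def test_matches_grey_opening_oracle(self):
        """The background equals a grey opening by a ball-shaped function."""
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 200, size=(40, 40))
        img = ndi.gaussian_filter(img, 2)
        r = 6
        bg_oracle = ndi.grey_opening(img, structure=_ball_profile(r))
        out = subtract_background(img, r)
        np.testing.assert_allclose(out, np.clip(img - bg_oracle, 0, None), atol=1e-7)

    def test_bad_radius(self):
        with pytest.raises(ValueError):
            subtract_background(np.zeros((5, 5)), 0)


def _terminal_image(speck_amplitude=120.0):
    img = np.full((120, 120), 8.0)
    img[50:70, 10:110] += 120.0  # 20x100 bar terminal
    img[15:20, 15:21] += speck_amplitude  # 30 px speck
    img[100:105, 90:96] += speck_amplitude  # 30 px speck
    return img


class TestSegmentOutline:
    def test_small_particle_filter_removes_specks(self):
        roi = RoiMask(np.ones((120, 120), bool))
        out = segment_outline(_terminal_image(), roi, min_particle=100, filter_on=True)
        assert not out.no_terminal
        labels, n = ndi.label(out.mask, structure=np.ones((3, 3)))
        assert n == 1  # only the terminal bar survives
        ys, xs = np.nonzero(out.mask)
        assert out.mask.sum() >= 500
        assert 50 <= ys.min() and ys.max() < 70  # inside the bar
        assert not out.mask[17, 17]

    def test_filter_off_keeps_specks(self):
        roi = RoiMask(np.ones((120, 120), bool))
        out = segment_outline(_terminal_image(), roi, min_particle=100, filter_on=False)
        labels, n = ndi.label(out.mask, structure=np.ones((3, 3)))
        assert n == 3

    def test_blank_roi_flags_no_terminal(self):
        img = np.full((60, 60), 5.0)
        roi = RoiMask(np.ones((60, 60), bool))
        out = segment_outline(img, roi)
        assert out.no_terminal

    def test_threshold_computed_within_roi_only(self):
        """Bright structure outside the ROI must not affect segmentation."""
        img = _terminal_image(0.0)
        roi_mask = np.zeros((120, 120), bool)
        roi_mask[40:80, :] = True
        out1 = segment_outline(img, RoiMask(roi_mask))
        img2 = img.copy()
        img2[:30, :] += 5000.0  # huge structure outside ROI
        out2 = segment_outline(img2, RoiMask(roi_mask))
        np.testing.assert_array_equal(out1.mask, out2.mask)


class TestAreaPerimeter:
    def test_area_at_widefield_calibration(self, cal_widefield):
        m = np.zeros((100, 100), bool)
        m.ravel()[:4806] = True
        assert measure_area(OutlineMask(m), cal_widefield) == pytest.approx(100.0, abs=0.05)

    def test_area_single_pixel(self, cal_unit):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        assert measure_area(OutlineMask(m), cal_unit) == 1.0

    def test_area_matches_count_and_is_additive(self, cal_unit):
        rng = np.random.default_rng(4)
        m = rng.random((30, 30)) > 0.6
        m[0, 0] = True
        count = sum(1 for v in m.ravel() if v)
        assert measure_area(OutlineMask(m), cal_unit) == count
        a = np.zeros((30, 30), bool)
        b = np.zeros((30, 30), bool)
        a[2:6, 2:6] = True
        b[20:26, 20:27] = True
        total = measure_area(OutlineMask(a | b), cal_unit)
        assert total == measure_area(OutlineMask(a), cal_unit) + measure_area(
            OutlineMask(b), cal_unit
        )

    def test_perimeter_square(self, cal_unit):
        m = np.zeros((20, 20), bool)
        m[4:15, 4:15] = True  # 11x11 filled square
        assert measure_perimeter(OutlineMask(m), cal_unit) == pytest.approx(40.0)

    def test_perimeter_single_pixel_is_zero(self, cal_unit):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        assert measure_perimeter(OutlineMask(m), cal_unit) == 0.0

    def test_perimeter_disc_approaches_circle(self, cal_unit):
        m = disc_mask((121, 121), (60, 60), 50)
        p = measure_perimeter(OutlineMask(m), cal_unit)
        assert abs(p - 2 * np.pi * 50) / (2 * np.pi * 50) < 0.05

    def test_perimeter_includes_hole_contour(self, cal_unit):
        m = np.zeros((20, 20), bool)
        m[4:15, 4:15] = True
        outer = measure_perimeter(OutlineMask(m), cal_unit)
        m[9, 9] = False
        assert measure_perimeter(OutlineMask(m), cal_unit) > outer

    def test_empty_mask_errors(self, cal_unit):
        with pytest.raises(ValueError):
            measure_area(OutlineMask(np.zeros((5, 5), bool)), cal_unit)
        with pytest.raises(ValueError):
            measure_perimeter(OutlineMask(np.zeros((5, 5), bool)), cal_unit)


class TestBoutonWatershed:
    def test_single_disc_one_bouton(self):
        m = disc_mask((50, 50), (25, 25), 12)
        assert count_boutons_watershed(OutlineMask(m)).count == 1

    def test_two_overlapping_discs_split(self):
        m = disc_mask((40, 60), (20, 20), 10) | disc_mask((40, 60), (20, 36), 10)
        assert count_boutons_watershed(OutlineMask(m)).count == 2

    def test_disc_below_area_floor_not_counted(self):
        m = disc_mask((13, 13), (6, 6), 5)
        assert m.sum() < 100
        assert count_boutons_watershed(OutlineMask(m), min_bouton_area=100).count == 0

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5, 6])
    def test_disc_chain_counts(self, k):
        bs = count_boutons_watershed(OutlineMask(disc_chain(k)))
        assert bs.count == k
        assert all(a >= 100 for a in bs.areas)

    def test_empty_mask_zero_boutons(self):
        bs = count_boutons_watershed(OutlineMask(np.zeros((10, 10), bool)))
        assert bs.count == 0


def test_remove_small_particles_strictness():
    m = np.zeros((20, 20), bool)
    m[0:3, 0:3] = True  # 9 px
    m[10:14, 10:14] = True  # 16 px
    out = remove_small_particles(m, 10)
    assert not out[1, 1] and out[11, 11]
    out = remove_small_particles(m, 16)
    assert out[11, 11]  # components of exactly min_size are kept
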