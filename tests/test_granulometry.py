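"""Morphological pyramids and local pattern spectra."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from retipatch import granulometry as gran
from retipatch.granulometry import (
    SEFamily,
    angular_spectrum,
    build_pyramid,
    dilate,
    erode,
    pattern_spectrum_local,
)

from _oracles import closing_oracle, opening_oracle, spectrum_oracle

SE = SEFamily(shape="disc", step=2, nmax=22)


class TestStructuringElements:
    @pytest.mark.parametrize("n", [1, 3, 7, 14])
    def test_disc_erosion_equals_scipy_footprint_erosion(self, rng, n):
        image = rng.random((48, 48))
        fp = gran.disc_footprint(n)
        expected = ndi.grey_erosion(image, footprint=fp, mode="reflect")
        np.testing.assert_array_equal(erode(image, n, "disc"), expected)

    @pytest.mark.parametrize("n", [1, 5, 11])
    def test_disc_dilation_equals_scipy_footprint_dilation(self, rng, n):
        image = rng.random((48, 48))
        fp = gran.disc_footprint(n)
        expected = ndi.grey_dilation(image, footprint=fp, mode="reflect")
        np.testing.assert_array_equal(dilate(image, n, "disc"), expected)

    @pytest.mark.parametrize("angle", [0, 45, 90, 135])
    def test_line_footprints_have_odd_support(self, angle):
        fp = gran.line_footprint(5, angle)
        assert fp.shape == (11, 11)
        assert fp.sum() == 11
        assert fp[5, 5]  # centered


class TestPyramid:
    def test_level_count_for_step2_nmax22(self, rng):
        pyr = build_pyramid(rng.random((48, 48)), "opening", SE)
        assert pyr.n_levels == 12
        np.testing.assert_array_equal(pyr.sizes, np.arange(0, 23, 2))

    def test_constant_image_is_fixed_point(self):
        image = np.full((48, 48), 0.6)
        for op in ("opening", "closing"):
            pyr = build_pyramid(image, op, SE)
            for lvl in pyr.levels:
                np.testing.assert_array_equal(lvl, image)

    def test_bright_square_vanishes_at_matching_disc_size(self):
        """A 5x5 bright square is removed by the first opening whose disc no
        longer fits inside it; every level matches the scipy oracle."""
        image = np.zeros((40, 40))
        image[18:23, 18:23] = 1.0
        se = SEFamily(shape="disc", step=1, nmax=5)
        pyr = build_pyramid(image, "opening", se)
        for lvl, n in zip(pyr.levels, se.sizes):
            np.testing.assert_allclose(lvl, opening_oracle(image, int(n)), atol=1e-12)
        survives = [lvl.max() > 0.5 for lvl in pyr.levels]
        assert survives[:3] == [True, True, True]  # discs up to radius 2 fit a 5x5 square
        assert not any(survives[3:])  # radius 3 disc (diameter 7) does not

    def test_openings_are_anti_extensive_and_closings_extensive(self, rng):
        image = rng.random((48, 48))
        po = build_pyramid(image, "opening", SE)
        pc = build_pyramid(image, "closing", SE)
        for lo, lc in zip(po.levels, pc.levels):
            assert np.all(lo <= image + 1e-12)
            assert np.all(lc >= image - 1e-12)

    def test_se_larger_than_image_rejected(self, rng):
        with pytest.raises(ValueError):
            build_pyramid(rng.random((16, 16)), "opening", SE)


class TestPatternSpectrum:
    def test_constant_patch_gives_zero_spectrum(self):
        image = np.full((48, 48), 0.4)
        ps = pattern_spectrum_local(
            build_pyramid(image, "opening", SE), build_pyramid(image, "closing", SE),
            (8, 8, 32, 32),
        )
        np.testing.assert_array_equal(ps.values, 0.0)

    def test_signed_layout_and_center_zero(self, rng):
        image = rng.random((48, 48))
        ps = pattern_spectrum_local(
            build_pyramid(image, "opening", SE), build_pyramid(image, "closing", SE),
            (8, 8, 32, 32),
        )
        assert len(ps.values) == 23
        np.testing.assert_array_equal(ps.sizes, np.r_[np.arange(-22, 0, 2), np.arange(0, 23, 2)])
        assert ps.values[11] == 0.0
        assert np.all(ps.values >= -1e-9)

    def test_positive_side_telescopes(self, rng):
        image = rng.random((48, 48))
        po = build_pyramid(image, "opening", SE)
        pc = build_pyramid(image, "closing", SE)
        bounds = (8, 8, 32, 32)
        ps = pattern_spectrum_local(po, pc, bounds)
        win = np.s_[8:40, 8:40]
        expected = (po.levels[0][win].sum() - po.levels[-1][win].sum()) / po.levels[0][win].sum()
        assert ps.positive.sum() == pytest.approx(expected, abs=1e-12)

    def test_bright_disc_peaks_at_its_size(self):
        """One radius-3 bright disc on a flat background concentrates the
        opening spectrum at the first level whose disc exceeds radius 3."""
        image = np.full((48, 48), 0.2)
        yy, xx = np.ogrid[:48, :48]
        image[(yy - 24) ** 2 + (xx - 24) ** 2 <= 9] = 0.9
        se = SEFamily(shape="disc", step=2, nmax=8)
        bounds = (12, 12, 24, 24)
        po = build_pyramid(image, "opening", se)
        pc = build_pyramid(image, "closing", se)
        ps = pattern_spectrum_local(po, pc, bounds)
        oracle = spectrum_oracle(image, bounds, se.sizes, op="opening")
        np.testing.assert_allclose(ps.positive, oracle, atol=1e-9)
        # sizes grid 0,2,4,6,8: the disc of radius 4 (entry for the 2->4
        # transition is index 1; 4 > 3 removes the blob) dominates
        assert np.argmax(ps.positive) == 1

    def test_spectra_identical_when_pyramids_rebuilt(self, rng):
        image = rng.random((48, 48))
        bounds = (4, 6, 32, 32)
        a = pattern_spectrum_local(
            build_pyramid(image, "opening", SE), build_pyramid(image, "closing", SE), bounds
        )
        b = pattern_spectrum_local(
            build_pyramid(image, "opening", SE), build_pyramid(image, "closing", SE), bounds
        )
        np.testing.assert_array_equal(a.values, b.values)

    def test_closing_side_matches_scipy_oracle(self, rng):
        image = rng.random((40, 40))
        se = SEFamily(shape="disc", step=2, nmax=6)
        bounds = (8, 8, 24, 24)
        ps = pattern_spectrum_local(
            build_pyramid(image, "opening", se), build_pyramid(image, "closing", se), bounds
        )
        oracle = spectrum_oracle(image, bounds, se.sizes, op="closing")
        np.testing.assert_allclose(ps.negative[::-1], oracle, atol=1e-9)

    def test_zero_volume_patch_flagged(self):
        image = np.zeros((48, 48))
        with pytest.warns(UserWarning, match="zero patch volume"):
            ps = pattern_spectrum_local(
                build_pyramid(image, "opening", SE),
                build_pyramid(image, "closing", SE),
                (8, 8, 16, 16),
            )
        assert ps.degenerate
        np.testing.assert_array_equal(ps.values, 0.0)


class TestAngularSpectrum:
    LINE = SEFamily(shape="line", step=2, nmax=8)

    def test_constant_patch_zero_at_all_angles(self):
        image = np.full((40, 40), 0.5)
        spectra = angular_spectrum(image, (8, 8, 24, 24), self.LINE, combine="concat")
        for ps in spectra:
            np.testing.assert_array_equal(ps.values, 0.0)

    def test_isotropic_texture_gives_similar_angle_spectra(self, rng):
        image = ndi.gaussian_filter(rng.random((64, 64)), 1.0)
        spectra = angular_spectrum(image, (16, 16, 32, 32), self.LINE, combine="concat")
        stacks = np.array([s.values for s in spectra])
        spread = stacks.std(axis=0).max()
        assert spread < 0.05  # no orientation preference on isotropic noise

    def test_horizontal_bar_is_removed_by_vertical_lines_first(self):
        image = np.full((40, 40), 0.1)
        image[19:22, 8:32] = 0.9  # bright bar: 24 px long, 3 px thick
        bounds = (10, 6, 24, 30)
        se = SEFamily(shape="line", step=2, nmax=8, angles=(0, 90))
        s0, s90 = angular_spectrum(image, bounds, se, combine="concat")
        # a 0-degree line up to length 17 fits inside the bar: nothing removed
        assert s0.positive.sum() == pytest.approx(0.0, abs=1e-9)
        # vertical lines longer than the 3 px thickness erase it immediately
        assert s90.positive[0] > 0.1
        assert np.argmax(s90.positive) == 0

    def test_mean_combination_averages_the_angle_curves(self, rng):
        image = rng.random((40, 40))
        bounds = (8, 8, 24, 24)
        mean_ps = angular_spectrum(image, bounds, self.LINE, combine="mean")
        concat = angular_spectrum(image, bounds, self.LINE, combine="concat")
        np.testing.assert_allclose(
            mean_ps.values, np.mean([s.values for s in concat], axis=0), atol=1e-12
        )
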