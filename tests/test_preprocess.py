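"""Conditioning pipeline: resolution, color, vessel segmentation, inpainting."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from retipatch.preprocess import (
    PreprocessConfig,
    condition,
    estimate_fov_mask,
    inpaint_vessels,
    normalize_color,
    normalize_resolution,
    segment_vessels,
)


class TestResolution:
    def test_constant_image_stays_constant(self):
        image = np.full((64, 64, 3), 0.3)
        out = normalize_resolution(image, PreprocessConfig(target_width=32, target_height=32))
        assert out.shape == (32, 32, 3)
        np.testing.assert_allclose(out, 0.3, atol=1e-12)

    def test_bright_pixel_survives_downscale_via_max_filter(self):
        """A single bright pixel must survive a 2x downscale: the size-3 max
        filter grows it into a 3x3 block first (brute-force oracle), and at
        least one resampled pixel keeps the full value."""
        image = np.zeros((64, 64))
        image[31, 33] = 1.0
        # brute-force oracle for the filter stage
        expected_block = np.zeros_like(image)
        for i in range(64):
            for j in range(64):
                expected_block[i, j] = image[max(0, i - 1):i + 2, max(0, j - 1):j + 2].max()
        filtered = ndi.maximum_filter(image, size=3)
        np.testing.assert_array_equal(filtered, expected_block)
        out = normalize_resolution(image, PreprocessConfig(target_width=32, target_height=32))
        assert out.max() == pytest.approx(1.0, abs=1e-12)

    def test_dark_polarity_uses_minimum_filter(self):
        image = np.ones((64, 64))
        image[10, 10] = 0.0
        cfg = PreprocessConfig(target_width=32, target_height=32, lesion_polarity="dark")
        out = normalize_resolution(image, cfg)
        assert out.min() == pytest.approx(0.0, abs=1e-12)

    def test_equal_dims_still_applies_extremum_filter(self):
        image = np.zeros((16, 16))
        image[8, 8] = 1.0
        out = normalize_resolution(image, PreprocessConfig())
        assert out.shape == (16, 16)
        assert out[7:10, 7:10].min() == 1.0  # dilated by the max filter

    def test_upscaling_refused(self):
        with pytest.raises(ValueError):
            normalize_resolution(np.zeros((16, 16)), PreprocessConfig(target_width=32, target_height=32))

    def test_even_filter_size_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(extremum_filter_size=4)


class TestColor:
    def _fov(self, shape=(32, 32)):
        fov = np.zeros(shape, dtype=bool)
        fov[4:28, 4:28] = True
        return fov

    def test_mean_is_matched_inside_fov(self, rng):
        fov = self._fov()
        image = 0.25 + 0.05 * rng.random((32, 32))
        out = normalize_color(image, fov, reference_mean=0.5)
        assert out[fov].mean() == pytest.approx(0.5, abs=1e-6)

    def test_outside_fov_untouched(self, rng):
        fov = self._fov()
        image = rng.random((32, 32, 3)) * 0.5
        out = normalize_color(image, fov, reference_mean=(0.5, 0.5, 0.5))
        np.testing.assert_array_equal(out[~fov], image[~fov])

    def test_image_at_reference_is_fixed_point(self, rng):
        fov = self._fov()
        image = np.clip(0.5 + 0.05 * rng.standard_normal((32, 32)), 0, 1)
        mu, sd = image[fov].mean(), image[fov].std()
        out = normalize_color(image, fov, reference_mean=mu, reference_std=sd)
        np.testing.assert_allclose(out[fov], image[fov], atol=1e-9)

    def test_constant_channel_falls_back_to_mean_shift(self):
        fov = self._fov()
        image = np.zeros((32, 32))
        out = normalize_color(image, fov, reference_mean=0.5, reference_std=0.1)
        np.testing.assert_allclose(out[fov], 0.5, atol=1e-12)

    def test_idempotence(self, rng):
        fov = self._fov()
        image = np.clip(0.4 + 0.08 * rng.standard_normal((32, 32)), 0, 1)
        once = normalize_color(image, fov, reference_mean=0.45, reference_std=0.05)
        twice = normalize_color(once, fov, reference_mean=0.45, reference_std=0.05)
        np.testing.assert_allclose(twice, once, atol=1e-6)

    def test_empty_fov_rejected(self):
        with pytest.raises(ValueError):
            normalize_color(np.zeros((8, 8)), np.zeros((8, 8), bool), reference_mean=0.5)


class TestVesselSegmentation:
    def test_constant_image_yields_empty_mask(self):
        fov = np.ones((64, 64), dtype=bool)
        assert not segment_vessels(np.full((64, 64), 0.5), fov).any()

    def test_synthetic_strokes_recovered(self, small_sample):
        green = small_sample.image[..., 1]
        mask = segment_vessels(green, small_sample.fov_mask)
        centerline = small_sample.vessel_centerline
        recall = (mask & centerline).sum() / centerline.sum()
        assert recall >= 0.7

    def test_mask_fraction_capped(self, rng):
        fov = np.ones((64, 64), dtype=bool)
        noisy = rng.random((64, 64))  # pathological input: everything is "structure"
        mask = segment_vessels(noisy, fov)
        assert mask.sum() / fov.sum() <= 0.30 + 1e-9


class TestInpainting:
    def test_empty_mask_is_identity(self, rng):
        green = rng.random((32, 32))
        np.testing.assert_array_equal(inpaint_vessels(green, np.zeros((32, 32), bool)), green)

    def test_constant_image_stays_constant(self):
        green = np.full((32, 32), 0.6)
        mask = np.zeros((32, 32), bool)
        mask[10:20, 10:12] = True
        np.testing.assert_allclose(inpaint_vessels(green, mask), 0.6, atol=1e-12)

    def test_dark_line_restored_to_background_level(self):
        green = np.full((32, 32), 0.6)
        mask = np.zeros((32, 32), bool)
        mask[:, 16] = True
        green[mask] = 0.1
        out = inpaint_vessels(green, mask)
        assert np.all(out[mask] >= 0.55) and np.all(out[mask] <= 0.65)

    def test_values_stay_in_observed_range(self, rng):
        green = 0.2 + 0.6 * rng.random((32, 32))
        mask = rng.random((32, 32)) < 0.1
        out = inpaint_vessels(green, mask)
        assert out.min() >= green.min() - 1e-12
        assert out.max() <= green.max() + 1e-12
        np.testing.assert_array_equal(out[~mask], green[~mask])

    def test_total_mask_rejected(self):
        with pytest.raises(ValueError):
            inpaint_vessels(np.zeros((8, 8)), np.ones((8, 8), bool))


class TestPipeline:
    def test_provenance_records_fixed_order(self, conditioned):
        steps = conditioned.provenance
        applied = [s.split("[")[0] for s in steps]
        expected = ["normalize_resolution", "segment_vessels", "inpaint_vessels", "extract_green"]
        assert [s for s in applied if s in expected] == expected

    def test_green_is_finite_inside_fov(self, conditioned):
        assert np.isfinite(conditioned.green[conditioned.fov_mask]).all()

    def test_fov_estimation_finds_the_disc(self, small_sample):
        est = estimate_fov_mask(small_sample.image)
        true = small_sample.fov_mask
        iou = (est & true).sum() / (est | true).sum()
        assert iou > 0.9

    def test_color_step_runs_when_reference_given(self, small_sample):
        cfg = PreprocessConfig(reference_mean=(0.5, 0.45, 0.15))
        cond = condition(small_sample.image, cfg, small_sample.fov_mask, small_sample.od_mask)
        assert any(s.startswith("normalize_color") for s in cond.provenance)
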