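"""Calibration, filtering, isocontour segmentation and SUV extraction."""

import numpy as np
import pytest

from acdose.errors import ConfigurationError, InvalidInputError, SegmentationError
from acdose.imaging import (
    WINDOW_BI213,
    WINDOW_FR221,
    CalibrationFactor,
    QuantImage,
    VOIMask,
    apply_calibration,
    compute_calibration_factor,
    gaussian_postfilter,
    isocontour_mask,
    voi_quant,
)

VS = (4.7952, 4.7952, 4.7952)


def _image(data, units="cps/voxel", window=WINDOW_BI213, t=24.0):
    return QuantImage(np.asarray(data, float), VS, units, t, window)


def _full_mask(shape, label="voi"):
    return VOIMask(np.ones(shape, bool), label)


class TestCalibration:
    @pytest.mark.parametrize("c", [0.5, 1.0, 3.7e-4])
    def test_uniform_ratio_definition(self, c):
        img = _image(np.full((8, 8, 8), 524.0 * c))
        factor = compute_calibration_factor(img, 524.0, _full_mask((8, 8, 8)))
        assert factor.value == pytest.approx(c, rel=1e-12)

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        img = _image(rng.uniform(1, 5, (6, 6, 6)))
        factor = CalibrationFactor(2.5e-4, WINDOW_BI213)
        cal = apply_calibration(img, factor)
        assert cal.units == "Bq/ml"
        back = cal.voxels * factor.value
        np.testing.assert_allclose(back, img.voxels, rtol=1e-12)

    def test_window_mismatch_rejected(self):
        img = _image(np.ones((4, 4, 4)))
        with pytest.raises(ConfigurationError):
            apply_calibration(img, CalibrationFactor(1.0, WINDOW_FR221))

    def test_zero_concentration_rejected(self):
        img = _image(np.ones((4, 4, 4)))
        with pytest.raises(InvalidInputError):
            compute_calibration_factor(img, 0.0, _full_mask((4, 4, 4)))

    def test_noisy_phantom_recovers_truth_within_standard_error(self):
        truth = 3.0e-4
        conc = 524.0
        count_time = 3360.0
        rng = np.random.default_rng(21)
        expected = conc * truth * count_time
        cps = rng.poisson(expected, size=(20, 20, 20)) / count_time
        img = _image(cps)
        factor = compute_calibration_factor(img, conc, _full_mask((20, 20, 20)))
        se = np.sqrt(expected / 20**3) / count_time / conc
        assert abs(factor.value - truth) < 3 * se


class TestGaussianFilter:
    def test_zero_fwhm_is_identity(self):
        rng = np.random.default_rng(1)
        img = _image(rng.uniform(0, 1, (8, 8, 8)), units="Bq/ml")
        out = gaussian_postfilter(img, 0.0)
        np.testing.assert_array_equal(out.voxels, img.voxels)

    def test_conserves_total_for_interior_support(self):
        data = np.zeros((40, 40, 40))
        data[15:25, 15:25, 15:25] = 7.3
        img = _image(data, units="Bq/ml")
        out = gaussian_postfilter(img, 30.0)
        assert out.voxels.sum() == pytest.approx(data.sum(), rel=1e-6)

    def test_delta_impulse_matches_sampled_gaussian(self):
        """A point source filtered at 30 mm FWHM becomes a discrete Gaussian
        with σ ≈ 2.657 voxels at 4.7952 mm voxels."""
        data = np.zeros((41, 41, 41))
        data[20, 20, 20] = 1.0
        out = gaussian_postfilter(_image(data, units="Bq/ml"), 30.0)
        sigma_vox = 30.0 / (2 * np.sqrt(2 * np.log(2))) / VS[0]
        assert sigma_vox == pytest.approx(2.657, abs=2e-3)
        # second moment of the filtered impulse along each axis equals σ²
        idx = np.arange(41) - 20.0
        for axis in range(3):
            marg = out.voxels.sum(axis=tuple(a for a in range(3) if a != axis))
            var = (marg * idx**2).sum() / marg.sum()
            assert np.sqrt(var) == pytest.approx(sigma_vox, rel=1e-3)
        # profile matches the closed-form Gaussian sampled on the grid
        center_profile = out.voxels[20, 20, :]
        analytic = np.exp(-(idx**2) / (2 * sigma_vox**2))
        analytic /= analytic.sum()
        # compare shape along the axis through the impulse (normalized)
        np.testing.assert_allclose(
            center_profile / center_profile.max(), analytic / analytic.max(), atol=5e-3
        )

    def test_uniform_image_interior_unchanged(self):
        img = _image(np.full((30, 30, 30), 2.0), units="Bq/ml")
        out = gaussian_postfilter(img, 10.0)
        assert out.voxels[15, 15, 15] == pytest.approx(2.0, rel=1e-6)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(InvalidInputError):
            gaussian_postfilter(_image(np.ones((4, 4, 4))), -1.0)


def _sphere(shape, center, radius):
    grids = np.indices(shape)
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return r2 <= radius**2


class TestIsocontour:
    def test_sharp_sphere_core(self):
        """A radially decreasing profile thresholds at exactly its ≥80% core."""
        shape = (31, 31, 31)
        grids = np.indices(shape)
        r = np.sqrt(sum((g - 15.0) ** 2 for g in grids))
        data = np.clip(1.0 - r / 12.0, 0.0, None)  # cone peaking at 1
        img = _image(data, units="Bq/ml")
        region = VOIMask(_sphere(shape, (15, 15, 15), 14), "search")
        mask = isocontour_mask(img, region, 0.8)
        np.testing.assert_array_equal(mask.voxels, data >= 0.8)

    def test_fraction_near_one_single_voxel(self):
        data = np.zeros((9, 9, 9))
        data[4, 4, 4] = 10.0
        data[4, 4, 5] = 9.0
        mask = isocontour_mask(_image(data, units="Bq/ml"), _full_mask((9, 9, 9)), 0.99)
        assert mask.n_voxels == 1

    def test_monotone_shrinking_in_fraction(self):
        rng = np.random.default_rng(4)
        data = rng.uniform(0, 1, (12, 12, 12))
        data[6, 6, 6] = 2.0
        img = _image(data, units="Bq/ml")
        region = _full_mask((12, 12, 12))
        prev = None
        for frac in (0.3, 0.5, 0.7, 0.9):
            mask = isocontour_mask(img, region, frac)
            if prev is not None:
                assert np.all(prev.voxels | ~mask.voxels)  # mask ⊆ prev
                assert mask.n_voxels <= prev.n_voxels
            prev = mask

    def test_two_equal_maxima_keeps_first_in_scan_order(self):
        data = np.zeros((11, 11, 11))
        data[2, 2, 2] = 5.0
        data[8, 8, 8] = 5.0
        img = _image(data, units="Bq/ml")
        with pytest.warns(UserWarning, match="equal maxima"):
            mask = isocontour_mask(img, _full_mask((11, 11, 11)), 0.8)
        assert mask.voxels[2, 2, 2] and not mask.voxels[8, 8, 8]

    def test_restricted_to_search_region(self):
        data = np.zeros((11, 11, 11))
        data[2, 2, 2] = 5.0   # outside the region
        data[8, 8, 8] = 3.0   # inside
        region = VOIMask(_sphere((11, 11, 11), (8, 8, 8), 2), "search")
        mask = isocontour_mask(_image(data, units="Bq/ml"), region, 0.8)
        assert mask.voxels[8, 8, 8] and not mask.voxels[2, 2, 2]


class TestVoiQuant:
    def test_suv_definition(self):
        injected, weight = 7.7, 77.0  # Bq/g normalization = 1e5
        conc = injected * 1e6 / (weight * 1000.0)
        img = _image(np.full((6, 6, 6), conc), units="Bq/ml")
        q = voi_quant(img, _full_mask((6, 6, 6)), injected, weight)
        assert q.suv_mean == pytest.approx(1.0, rel=1e-12)

    def test_total_activity_is_conc_times_volume(self):
        img = _image(np.full((6, 6, 6), 100.0), units="Bq/ml")
        mask = VOIMask(_sphere((6, 6, 6), (3, 3, 3), 2), "voi")
        q = voi_quant(img, mask, 7.7, 77.0)
        voxel_ml = np.prod(VS) / 1000.0
        assert q.volume == pytest.approx(mask.n_voxels * voxel_ml, rel=1e-12)
        assert q.total_activity == pytest.approx(100.0 * q.volume, rel=1e-9)
        assert q.total_activity == pytest.approx(q.mean_concentration * q.volume, rel=1e-9)

    def test_linear_in_voxel_values(self):
        rng = np.random.default_rng(8)
        data = rng.uniform(10, 50, (6, 6, 6))
        mask = _full_mask((6, 6, 6))
        q1 = voi_quant(_image(data, units="Bq/ml"), mask, 7.7, 77.0)
        q2 = voi_quant(_image(3.0 * data, units="Bq/ml"), mask, 7.7, 77.0)
        assert q2.suv_mean == pytest.approx(3.0 * q1.suv_mean, rel=1e-12)
        assert q2.total_activity == pytest.approx(3.0 * q1.total_activity, rel=1e-12)

    def test_unit_mismatch_rejected(self):
        img = _image(np.ones((4, 4, 4)), units="cps/voxel")
        with pytest.raises(ConfigurationError):
            voi_quant(img, _full_mask((4, 4, 4)), 7.7, 77.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(SegmentationError):
            VOIMask(np.zeros((4, 4, 4), bool), "empty")
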