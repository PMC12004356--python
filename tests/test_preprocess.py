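"""Preprocessing contracts: crop, baseline recovery, map reduction, SNR, scaling."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from serstdm.preprocess import (
    ReductionConfig,
    Scaler,
    baseline_correct,
    crop,
    map_reduce_top_fraction,
    peak_height,
    scale_dataset,
    snr,
)
from serstdm.types import SpectralMap, Spectrum

from conftest import lorentzian

AXIS = np.linspace(500.0, 1800.0, 400)


def _delta_map(heights, band=1559.0, axis=None):
    """Map whose pixels carry one band with prescribed peak heights."""
    axis = AXIS if axis is None else axis
    profile = lorentzian(axis, band, 14.0)
    X = np.array([h * profile for h in heights])
    coords = np.column_stack([np.arange(len(heights)), np.zeros(len(heights), int)])
    return SpectralMap(axis, X, coords)


class TestCrop:
    def test_full_range_is_identity(self):
        spec = Spectrum(AXIS, np.sin(AXIS / 50))
        out = crop(spec, (AXIS[0], AXIS[-1]))
        np.testing.assert_array_equal(out.axis, spec.axis)
        np.testing.assert_array_equal(out.intensities, spec.intensities)

    def test_containment(self):
        out = crop(Spectrum(AXIS, np.ones_like(AXIS)), (600.0, 1600.0))
        assert out.axis.min() >= 600.0 and out.axis.max() <= 1600.0

    @pytest.mark.parametrize("seed", range(10))
    def test_retained_count_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        lo, hi = np.sort(rng.uniform(AXIS[0], AXIS[-1], size=2))
        if not ((AXIS >= lo) & (AXIS <= hi)).any():
            return
        out = crop(Spectrum(AXIS, np.ones_like(AXIS)), (lo, hi))
        brute = sum(1 for v in AXIS if lo <= v <= hi)
        assert len(out) == brute

    def test_empty_intersection_raises(self):
        with pytest.raises(ValueError):
            crop(Spectrum(AXIS, np.ones_like(AXIS)), (2000.0, 2100.0))

    @given(
        st.tuples(
            st.floats(500, 1800), st.floats(500, 1800),
            st.floats(500, 1800), st.floats(500, 1800),
        )
    )
    def test_nested_crop_composition(self, bounds):
        """crop(outer) then crop(inner) equals crop(inner) for nested ranges."""
        a, b, c, d = sorted(bounds)
        inner, outer = (b, c), (a, d)
        spec = Spectrum(AXIS, np.cos(AXIS / 30))
        if not ((AXIS >= b) & (AXIS <= c)).any():
            return
        once = crop(spec, inner)
        twice = crop(crop(spec, outer), inner)
        np.testing.assert_array_equal(once.axis, twice.axis)
        np.testing.assert_array_equal(once.intensities, twice.intensities)


class TestBaselineCorrect:
    def test_pure_polynomial_baseline_removed(self):
        u = (AXIS - AXIS[0]) / (AXIS[-1] - AXIS[0])
        base = 120 - 60 * u + 40 * u**2
        out = baseline_correct(Spectrum(AXIS, base))
        assert np.abs(out.intensities).max() < 0.01 * np.ptp(base)

    def test_peak_heights_recovered_over_linear_baseline(self):
        base = 50 + 0.05 * AXIS
        peaks = 80 * lorentzian(AXIS, 1559, 18) + 40 * lorentzian(AXIS, 890, 14)
        out = baseline_correct(Spectrum(AXIS, base + peaks))
        assert abs(peak_height(out, 1559) - 80) < 0.05 * 80
        assert abs(peak_height(out, 890) - 40) < 0.05 * 40

    def test_stability_on_already_corrected_input(self):
        rng = np.random.default_rng(0)
        sd = 2.0
        clean = 60 * lorentzian(AXIS, 1559, 18)
        noisy = clean + rng.normal(0, sd, AXIS.size)
        out = baseline_correct(Spectrum(AXIS, noisy))
        before = peak_height(Spectrum(AXIS, noisy), 1559)
        after = peak_height(out, 1559)
        assert abs(after - before) < sd

    def test_rejects_nonfinite(self):
        bad = np.ones_like(AXIS)
        bad[3] = np.nan
        with pytest.raises(ValueError):
            baseline_correct(Spectrum(AXIS, bad))


class TestMapReduce:
    def test_full_fraction_is_channelwise_mean(self):
        rng = np.random.default_rng(1)
        smap = _delta_map(rng.uniform(1, 10, 12))
        cfg = ReductionConfig(fraction=1.0, crop_range=(500, 1800),
                              correct_baseline=False)
        red = map_reduce_top_fraction(smap, cfg)
        np.testing.assert_allclose(
            red.spectrum.intensities, smap.intensities.mean(axis=0), rtol=1e-12
        )

    def test_identical_pixels_reduce_to_that_pixel(self):
        smap = _delta_map([5.0] * 8)
        cfg = ReductionConfig(crop_range=(500, 1800), correct_baseline=False)
        red = map_reduce_top_fraction(smap, cfg)
        np.testing.assert_allclose(
            red.spectrum.intensities, smap.intensities[0], rtol=1e-12
        )

    def test_top_two_of_ten_ranked_pixels(self):
        """Heights 1..10 at fraction 0.2 average exactly the 9 and 10 pixels."""
        smap = _delta_map(np.arange(1.0, 11.0))
        cfg = ReductionConfig(crop_range=(500, 1800), correct_baseline=False)
        red = map_reduce_top_fraction(smap, cfg)
        np.testing.assert_allclose(
            red.spectrum.intensities,
            smap.intensities[[8, 9]].mean(axis=0),
            rtol=1e-12,
        )
        assert red.peak_height == pytest.approx(
            red.pixel_heights[[8, 9]].mean(), rel=1e-12
        )
        assert red.pixel_heights.argsort().tolist() == list(range(10))

    def test_selection_dominance(self):
        rng = np.random.default_rng(2)
        smap = _delta_map(rng.uniform(0.5, 20, 17))
        cfg = ReductionConfig(crop_range=(500, 1800), correct_baseline=False)
        red = map_reduce_top_fraction(smap, cfg)
        assert red.peak_height >= red.pixel_heights.mean()

    def test_invariant_under_pixel_permutation(self):
        rng = np.random.default_rng(3)
        heights = rng.uniform(1, 10, 15)
        cfg = ReductionConfig(crop_range=(500, 1800), correct_baseline=False)
        a = map_reduce_top_fraction(_delta_map(heights), cfg)
        b = map_reduce_top_fraction(_delta_map(heights[::-1]), cfg)
        np.testing.assert_allclose(
            a.spectrum.intensities, b.spectrum.intensities, rtol=1e-12
        )

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            ReductionConfig(fraction=0.0)


class TestSNR:
    def test_snr_scales_with_amplitude(self):
        rng = np.random.default_rng(4)
        noise = rng.normal(0, 2.0, AXIS.size)
        peak = lorentzian(AXIS, 1559, 18)
        s1 = snr(Spectrum(AXIS, 50 * peak + noise), correct_baseline=False)
        s2 = snr(Spectrum(AXIS, 100 * peak + noise), correct_baseline=False)
        # same noise realization, amplitude doubled where noise is negligible
        assert s2 / s1 == pytest.approx(2.0, rel=0.05)

    def test_recovers_injected_height_over_sigma(self):
        """Mean SNR over 500 noise draws approximates h / sigma."""
        h, sigma = 60.0, 3.0
        peak = h * lorentzian(AXIS, 1559, 18)
        rng = np.random.default_rng(5)
        vals = [
            snr(
                Spectrum(AXIS, peak + rng.normal(0, sigma, AXIS.size)),
                correct_baseline=False,
            )
            for _ in range(500)
        ]
        assert np.mean(vals) == pytest.approx(h / sigma, rel=0.1)

    def test_zero_noise_flagged_undefined(self):
        spike = np.zeros_like(AXIS)
        spike[int(np.argmin(np.abs(AXIS - 1559)))] = 10.0
        with pytest.raises(ValueError, match="undefined"):
            snr(Spectrum(AXIS, spike), correct_baseline=False)


class TestScaling:
    def test_minmax_column_example(self):
        X = np.array([[0.0], [5.0], [10.0]])
        Xs, _ = scale_dataset(X, "minmax")
        np.testing.assert_allclose(Xs.ravel(), [0.0, 0.5, 1.0])

    def test_minmax_training_range_is_unit_interval(self):
        rng = np.random.default_rng(6)
        Xs, _ = scale_dataset(rng.normal(size=(20, 30)), "minmax")
        np.testing.assert_allclose(Xs.min(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Xs.max(axis=0), 1.0, atol=1e-12)

    def test_minmax_idempotent_on_training_output(self):
        rng = np.random.default_rng(7)
        Xs, _ = scale_dataset(rng.normal(size=(10, 5)), "minmax")
        Xss, _ = scale_dataset(Xs, "minmax")
        np.testing.assert_allclose(Xss, Xs, atol=1e-12)

    def test_minmax_constant_column_maps_to_zero(self):
        X = np.array([[1.0, 3.0], [2.0, 3.0]])
        Xs, _ = scale_dataset(X, "minmax")
        np.testing.assert_array_equal(Xs[:, 1], [0.0, 0.0])

    def test_autoscale_recomputed_moments(self):
        rng = np.random.default_rng(8)
        Xs, _ = scale_dataset(rng.normal(size=(25, 12)), "autoscale")
        np.testing.assert_allclose(Xs.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Xs.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_autoscale_constant_column_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            scale_dataset(np.array([[1.0, 3.0], [2.0, 3.0]]), "autoscale")

    def test_stored_parameters_apply_to_new_rows(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(0, 10, size=(8, 4))
        _, scaler = scale_dataset(X, "minmax")
        new = rng.uniform(-5, 15, size=(3, 4))
        expected = (new - X.min(axis=0)) / (X.max(axis=0) - X.min(axis=0))
        np.testing.assert_allclose(scaler.transform(new), expected)

    def test_vector_norm_rows_unit_length(self):
        rng = np.random.default_rng(10)
        Xs, _ = scale_dataset(rng.normal(size=(6, 9)), "vector_norm")
        np.testing.assert_allclose(np.linalg.norm(Xs, axis=1), 1.0)

    def test_savgol_derivative_of_line_is_constant(self):
        row = np.linspace(0, 10, 50)
        Xs, _ = scale_dataset(row[None, :], "savgol_derivative")
        inner = Xs[0, 5:-5]
        np.testing.assert_allclose(inner, inner[0], atol=1e-9)

    def test_log_clips_negatives(self):
        Xs, _ = scale_dataset(np.array([[-1.0, 0.0, math.e - 1]]), "log")
        np.testing.assert_allclose(Xs, [[0.0, 0.0, 1.0]])
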