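"""Spectral features: Welch estimator, Parseval energy, the 10-feature set."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import signal as sps

from comaqeeg.bands import CANONICAL_BANDS, band_by_name
from comaqeeg.features import (
    FEATURE_NAMES,
    FeatureVector,
    PsdEstimate,
    WelchConfig,
    area_features,
    band_slice,
    extract_feature_vector,
    feature_column_names,
    parseval_energy,
    peak_features,
    power_features,
    vectors_to_frame,
    welch_psd,
)
from comaqeeg.segmentation import Segment

FS = 500.0
ALPHA = band_by_name("alpha")


class TestWelch:
    def test_zero_signal_gives_zero_psd(self):
        psd = welch_psd(np.zeros(2048), FS)
        assert np.all(psd.power == 0)

    def test_sinusoid_peak_at_its_frequency(self):
        t = np.arange(0, 20, 1 / FS)
        psd = welch_psd(np.sin(2 * np.pi * 10 * t), FS)
        peak_f = psd.frequencies[np.argmax(psd.power)]
        grid_step = psd.frequencies[1] - psd.frequencies[0]
        assert abs(peak_f - 10.0) <= grid_step

    def test_white_noise_integrated_psd_estimates_variance(self):
        rng = np.random.default_rng(0)
        sigma2 = 4.0
        x = rng.normal(0, np.sqrt(sigma2), int(60 * FS))
        psd = welch_psd(x, FS)
        integrated = np.trapezoid(psd.power, psd.frequencies)
        assert integrated == pytest.approx(np.var(x), rel=0.10)

    def test_matches_scipy_welch(self):
        """Independent estimator oracle: scipy's Welch, same settings."""
        x = np.random.default_rng(1).standard_normal(10000)
        cfg = WelchConfig()
        mine = welch_psd(x, FS, cfg)
        f, p = sps.welch(
            x, fs=FS, window=cfg.window_shape, nperseg=cfg.window_length,
            noverlap=int(cfg.window_length * cfg.overlap_fraction),
            nfft=cfg.n_fft, detrend=False, scaling="density",
        )
        np.testing.assert_allclose(mine.frequencies, f)
        np.testing.assert_allclose(mine.power, p, rtol=1e-10, atol=1e-15)

    def test_single_rectangular_window_equals_periodogram(self):
        """On a toy signal, one full-length boxcar window is the raw periodogram."""
        n = 64
        x = np.random.default_rng(2).standard_normal(n)
        cfg = WelchConfig(window_length=n, overlap_fraction=0.0, window_shape="boxcar", n_fft=n)
        mine = welch_psd(x, FS, cfg)
        # brute-force DFT periodogram, one-sided density scaling
        spectrum = np.abs(np.fft.rfft(x)) ** 2 / (FS * n)
        spectrum[1:] *= 2
        spectrum[-1] /= 2  # n even: Nyquist bin is not doubled
        np.testing.assert_allclose(mine.power, spectrum, rtol=1e-9)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            welch_psd(np.zeros(100), FS, WelchConfig(window_length=256))


class TestParseval:
    def test_zero_signal(self):
        assert parseval_energy(np.zeros(16)) == 0.0

    def test_ones_vector(self):
        assert parseval_energy(np.ones(4)) == pytest.approx(4.0)

    @given(st.integers(3, 400))
    def test_identity_with_time_domain(self, n):
        x = np.random.default_rng(n).normal(0, 3, n)
        assert parseval_energy(x) == pytest.approx(float(np.sum(x**2)), rel=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            parseval_energy(np.array([]))


class TestBandSlice:
    def test_alpha_slice_bounds(self):
        psd = welch_psd(np.random.default_rng(0).standard_normal(4096), FS)
        out = band_slice(psd, ALPHA)
        assert out.frequencies.min() >= 8.0
        assert out.frequencies.max() <= 13.0

    def test_idempotent(self):
        psd = welch_psd(np.random.default_rng(0).standard_normal(4096), FS)
        once = band_slice(psd, ALPHA)
        twice = band_slice(once, ALPHA)
        np.testing.assert_array_equal(once.frequencies, twice.frequencies)

    def test_delta_lower_bin_against_grid_scan(self):
        """Lowest retained delta bin = smallest grid frequency >= 0.5 Hz."""
        freqs = np.arange(0, 50, 0.98)
        psd = PsdEstimate(freqs, np.ones_like(freqs))
        out = band_slice(psd, band_by_name("delta"))
        expected = min(f for f in freqs if f >= 0.5)
        assert out.frequencies[0] == pytest.approx(expected)

    def test_empty_slice_is_error_naming_band(self):
        psd = PsdEstimate(np.array([100.0, 110.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="alpha"):
            band_slice(psd, ALPHA)


class TestPeakAndAreas:
    toy = PsdEstimate(
        np.array([8.0, 9.0, 10.0, 11.0, 12.0, 13.0]),
        np.array([0.0, 1.0, 4.0, 2.0, 1.0, 0.0]),
    )

    def test_peak_on_toy_grid(self):
        assert peak_features(self.toy) == (10.0, 4.0)

    def test_tie_broken_toward_lowest_frequency(self):
        psd = PsdEstimate(np.array([8.0, 9.0, 10.0]), np.array([3.0, 3.0, 1.0]))
        assert peak_features(psd) == (8.0, 3.0)

    def test_single_bin(self):
        psd = PsdEstimate(np.array([9.0]), np.array([2.5]))
        assert peak_features(psd) == (9.0, 2.5)

    def test_areas_on_toy_grid_match_trapezoid_oracle(self):
        a1, a2, r1, r2, r3 = area_features(self.toy, 10.0)
        assert a1 == pytest.approx(3.0)
        assert a2 == pytest.approx(5.0)
        assert r1 == pytest.approx(0.375)
        assert r2 == pytest.approx(3.0 / 5.0)
        assert r3 == pytest.approx(0.625)

    def test_symmetric_triangle_splits_evenly(self):
        psd = PsdEstimate(
            np.array([8.0, 9.0, 10.0, 11.0, 12.0]),
            np.array([0.0, 1.0, 2.0, 1.0, 0.0]),
        )
        a1, a2, r1, r2, r3 = area_features(psd, 10.0)
        assert r1 == pytest.approx(0.5)
        assert r2 == pytest.approx(1.0)
        assert r3 == pytest.approx(0.5)

    def test_peak_at_first_bin_degenerate_split(self):
        psd = PsdEstimate(np.array([8.0, 9.0, 10.0]), np.array([4.0, 1.0, 0.0]))
        a1, a2, r1, r2, r3 = area_features(psd, 8.0)
        assert (a1, r1, r3) == (0.0, 0.0, 1.0)
        assert r2 == 0.0

    def test_peak_at_last_bin_rate2_nan(self):
        psd = PsdEstimate(np.array([8.0, 9.0]), np.array([1.0, 2.0]))
        a1, a2, r1, r2, r3 = area_features(psd, 9.0)
        assert a2 == 0.0
        assert np.isnan(r2)

    def test_off_grid_maxf_rejected(self):
        with pytest.raises(ValueError):
            area_features(self.toy, 10.5)

    @given(st.integers(0, 1000))
    def test_rate_identities_on_random_psds(self, seed):
        rng = np.random.default_rng(seed)
        freqs = np.sort(rng.uniform(8, 13, 8))
        freqs += np.arange(8) * 1e-6  # strictly increasing
        powers = rng.uniform(0, 5, 8)
        maxf, _ = peak_features(PsdEstimate(freqs, powers))
        a1, a2, r1, r2, r3 = area_features(PsdEstimate(freqs, powers), maxf)
        assert a1 + a2 == pytest.approx(float(np.trapezoid(powers, freqs)), rel=1e-9)
        if a1 + a2 > 0:
            assert r1 + r3 == pytest.approx(1.0)
        if a2 > 0:
            assert r2 * r3 == pytest.approx(r1)


class TestPowerFeatures:
    def test_zero_psd(self):
        psd = PsdEstimate(np.array([1.0, 2.0]), np.zeros(2))
        assert power_features(psd, FS) == (0.0, 0.0)

    def test_single_bin_forced_values(self):
        psd = PsdEstimate(np.array([10.0]), np.array([2.0]))
        npow, tpow = power_features(psd, 500.0)
        assert tpow == pytest.approx(4.0)
        assert npow == pytest.approx(0.008)

    def test_tpower_is_fs_times_npower(self):
        psd = welch_psd(np.random.default_rng(3).standard_normal(4096), FS)
        npow, tpow = power_features(psd, FS)
        assert tpow == pytest.approx(FS * npow, rel=1e-12)


class TestFeatureVector:
    def test_length_160_in_16_blocks_of_10(self, toy_segment):
        vec = extract_feature_vector(toy_segment)
        assert vec.values.shape == (160,)
        names = feature_column_names()
        assert len(names) == 160
        blocks = {tuple(n.split("|")[:2]) for n in names}
        assert len(blocks) == 16
        for i, name in enumerate(names):
            assert name.endswith(FEATURE_NAMES[i % 10])

    def test_deterministic(self, toy_segment):
        a = extract_feature_vector(toy_segment)
        b = extract_feature_vector(toy_segment)
        np.testing.assert_array_equal(a.values, b.values)

    def test_wrong_channel_count_rejected(self, toy_segment):
        bad = Segment(
            patient_id="x", gcs=3, stage_name="nurse", window_label="FULL",
            samples=toy_segment.samples[:3], fs=FS,
        )
        with pytest.raises(ValueError, match="channels"):
            extract_feature_vector(bad)

    def test_scaling_monotonicity(self, toy_segment):
        """x -> c*x scales energy-like features by c^2, power sums by c^4,
        and leaves frequencies and area ratios unchanged."""
        c = 2.5
        base = extract_feature_vector(toy_segment).values
        scaled_seg = Segment(
            patient_id="x", gcs=3, stage_name="nurse", window_label="FULL",
            samples=toy_segment.samples * c, fs=toy_segment.fs,
        )
        scaled = extract_feature_vector(scaled_seg).values
        for i, name in enumerate(feature_column_names()):
            feat = name.split("|")[2]
            if feat in ("Energy", "Maxp", "AUC1", "AUC2"):
                assert scaled[i] == pytest.approx(base[i] * c**2, rel=1e-8)
            elif feat in ("NPower", "TPower"):
                assert scaled[i] == pytest.approx(base[i] * c**4, rel=1e-8)
            elif np.isfinite(base[i]):
                assert scaled[i] == pytest.approx(base[i], rel=1e-8)

    def test_vectors_to_frame_shape(self, toy_segment):
        frame = vectors_to_frame([extract_feature_vector(toy_segment)])
        assert frame.shape == (1, 164)
        assert list(frame.columns[:4]) == ["patient_id", "gcs", "stage_name", "window_label"]
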