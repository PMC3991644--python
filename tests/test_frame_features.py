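import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fricshape.corpus_io import FricativeGroup, PhoneToken
from fricshape.frame_features import (
    DEFAULT_BAND_HZ,
    FeatureSet,
    FrameMode,
    FrameSpectrum,
    compute_features,
    feature_dimension,
    fft_features,
    frame_token,
    gammatone_features,
    magnitude_spectrum,
    make_gammatone_bank,
    mfcc_features,
    spectral_moments,
    spectral_peak,
    spectral_slope,
)

from .conftest import FS, make_tone_token


def flat_spectrum(value=1.0, fs=FS, nfft=128):
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return FrameSpectrum(np.full(freqs.size, value), freqs, 8.0, fs)


def spectrum_with_db(db_by_freq: dict, base_db=40.0, fs=FS, nfft=128):
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    db = np.full(freqs.size, base_db)
    for f, v in db_by_freq.items():
        db[np.argmin(np.abs(freqs - f))] = v
    return FrameSpectrum(10.0 ** (db / 20.0), freqs, 8.0, fs)


def brute_force_moments(freqs, mags):
    """Independent oracle: explicit weighted sums over the power mass."""
    w = [m * m for m in mags]
    total = sum(w)
    p = [wi / total for wi in w]
    m1 = sum(f * pi for f, pi in zip(freqs, p))
    m2 = sum((f - m1) ** 2 * pi for f, pi in zip(freqs, p))
    m3 = sum((f - m1) ** 3 * pi for f, pi in zip(freqs, p)) / m2**1.5
    m4 = sum((f - m1) ** 4 * pi for f, pi in zip(freqs, p)) / m2**2 - 3.0
    return m1, m2, m3, m4


class TestFraming:
    def test_all_mode_drops_partial_tail(self):
        token = make_tone_token(2000.0, duration_ms=25.0)  # 400 samples
        frames = frame_token(token, mode=FrameMode.ALL)
        assert len(frames) == 3
        assert all(f.size == 128 for f in frames)

    def test_exactly_one_frame(self):
        token = make_tone_token(2000.0, duration_ms=8.0)
        assert len(frame_token(token, mode=FrameMode.ALL)) == 1

    def test_short_token_zero_padded(self):
        token = make_tone_token(2000.0, duration_ms=3.75)  # 60 samples
        frames = frame_token(token, mode=FrameMode.ALL)
        assert len(frames) == 1
        assert frames[0].size == 128
        assert np.all(frames[0][60:] == 0.0)

    def test_random_one_is_seeded(self):
        token = make_tone_token(2000.0, duration_ms=50.0)
        a = frame_token(token, mode=FrameMode.RANDOM_ONE, seed=4)[0]
        b = frame_token(token, mode=FrameMode.RANDOM_ONE, seed=4)[0]
        np.testing.assert_array_equal(a, b)

    def test_empty_token_rejected(self):
        token = PhoneToken("x", FricativeGroup.ALV, np.zeros(10), FS, "s")
        token.samples = np.array([])
        token.end = 0
        with pytest.raises(ValueError, match="empty"):
            frame_token(token)

    def test_too_short_frame_rejected(self):
        token = make_tone_token(2000.0)
        with pytest.raises(ValueError, match="too short"):
            frame_token(token, frame_ms=0.5)


class TestMagnitudeSpectrum:
    def test_bin_centered_cosine_peaks_at_its_bin(self):
        frame = make_tone_token(2000.0, duration_ms=8.0).samples
        s = magnitude_spectrum(frame, FS)
        assert np.argmax(s.magnitudes) == 16  # 2000 / 125
        assert s.bin_freqs_hz[16] == 2000.0

    def test_zero_frame_all_zero(self):
        s = magnitude_spectrum(np.zeros(128), FS)
        assert np.all(s.magnitudes == 0.0)

    def test_parseval(self, rng):
        frame = rng.normal(size=128)
        s = magnitude_spectrum(frame, FS)
        windowed = frame * np.hamming(128)
        full_energy = (
            s.magnitudes[0] ** 2
            + s.magnitudes[-1] ** 2
            + 2.0 * np.sum(s.magnitudes[1:-1] ** 2)
        )
        assert full_energy == pytest.approx(128 * np.sum(windowed**2), rel=1e-6)

    def test_non_power_of_two_rejected(self):
        with pytest.raises(ValueError, match="power of two"):
            magnitude_spectrum(np.zeros(100), FS, nfft=100)

    def test_frame_longer_than_nfft_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            magnitude_spectrum(np.zeros(256), FS, nfft=128)

    def test_bin_spacing(self):
        s = magnitude_spectrum(np.zeros(128), FS)
        assert s.bin_freqs_hz[1] - s.bin_freqs_hz[0] == 125.0
        assert s.magnitudes.size == 65


class TestSpectralMoments:
    def test_uniform_mass_mean_and_skew(self):
        mom = spectral_moments(flat_spectrum())
        assert mom.m1 == pytest.approx(4500.0)  # midpoint of [1000, 8000]
        assert mom.m3 == pytest.approx(0.0, abs=1e-12)

    def test_uniform_mass_excess_kurtosis(self):
        # discrete uniform over n bins: m4 = -6/5 * (n^2 + 1) / (n^2 - 1)
        n_bins = 57  # 1000..8000 Hz at 125-Hz spacing
        expected = -1.2 * (n_bins**2 + 1) / (n_bins**2 - 1)
        mom = spectral_moments(flat_spectrum())
        assert mom.m4 == pytest.approx(expected, rel=1e-9)
        assert mom.m4 == pytest.approx(-1.2, abs=0.01)

    def test_single_active_bin_degenerate(self):
        s = flat_spectrum(0.0)
        s.magnitudes[32] = 1.0  # 4000 Hz
        mom = spectral_moments(s)
        assert mom.m1 == 4000.0
        assert mom.m2 == 0.0
        assert mom.m3 == 0.0 and mom.m4 == 0.0
        assert mom.degenerate

    def test_all_zero_in_band_rejected(self):
        s = flat_spectrum(0.0)
        with pytest.raises(ValueError, match="zero"):
            spectral_moments(s)

    def test_brute_force_oracle_on_random_spectra(self, rng):
        for _ in range(20):
            s = flat_spectrum()
            s.magnitudes = rng.uniform(0.1, 2.0, size=s.magnitudes.size)
            mask = (s.bin_freqs_hz >= 1000) & (s.bin_freqs_hz <= 8000)
            oracle = brute_force_moments(
                list(s.bin_freqs_hz[mask]), list(s.magnitudes[mask])
            )
            mom = spectral_moments(s)
            for got, want in zip((mom.m1, mom.m2, mom.m3, mom.m4), oracle):
                assert got == pytest.approx(want, rel=1e-9, abs=1e-9)

    def test_frequency_shift_covariance(self, rng):
        base = flat_spectrum(0.0)
        # random power confined to 1000..6000 so a one-bin shift stays in band
        inner = (base.bin_freqs_hz >= 1000) & (base.bin_freqs_hz <= 6000)
        base.magnitudes[inner] = rng.uniform(0.5, 1.5, size=int(inner.sum()))
        shifted = flat_spectrum(0.0)
        shifted.magnitudes[1:] = base.magnitudes[:-1]
        a = spectral_moments(base)
        b = spectral_moments(shifted)
        assert b.m1 - a.m1 == pytest.approx(125.0, rel=1e-9)
        assert b.m2 == pytest.approx(a.m2, rel=1e-9)
        assert b.m3 == pytest.approx(a.m3, rel=1e-9, abs=1e-12)
        assert b.m4 == pytest.approx(a.m4, rel=1e-9)

    @settings(max_examples=20, deadline=None)
    @given(st.floats(0.01, 100.0), st.integers(0, 2**31 - 1))
    def test_amplitude_scale_invariance(self, gain, seed):
        s = flat_spectrum()
        s.magnitudes = np.random.default_rng(seed).uniform(0.1, 2.0, 65)
        scaled = FrameSpectrum(s.magnitudes * gain, s.bin_freqs_hz, 8.0, FS)
        a, b = spectral_moments(s), spectral_moments(scaled)
        assert b.m1 == pytest.approx(a.m1, rel=1e-9)
        assert b.m2 == pytest.approx(a.m2, rel=1e-9)
        assert b.m3 == pytest.approx(a.m3, rel=1e-6, abs=1e-9)
        assert b.m4 == pytest.approx(a.m4, rel=1e-6, abs=1e-9)
        assert spectral_peak(scaled) == spectral_peak(s)


class TestPeakAndSlope:
    def test_tone_peak(self):
        s = spectrum_with_db({4625.0: 60.0})
        assert spectral_peak(s) == 4625.0

    def test_tie_breaks_to_lowest_frequency(self):
        s = spectrum_with_db({2000.0: 60.0, 5000.0: 60.0})
        assert spectral_peak(s) == 2000.0

    def test_flat_spectrum_peak_is_lowest_in_band(self):
        assert spectral_peak(flat_spectrum()) == 1000.0

    def test_slope_positive_example(self):
        # 60 dB at 4625 Hz vs 20 dB at 1000 Hz -> 40 / 3625
        s = spectrum_with_db({4625.0: 60.0, 1000.0: 20.0})
        assert spectral_slope(s) == pytest.approx(40.0 / 3625.0, rel=1e-6)
        assert spectral_slope(s) == pytest.approx(0.011, abs=1.5e-3)

    def test_slope_negative_example(self):
        s = spectrum_with_db({1000.0: 60.0, 6000.0: 35.0})
        assert spectral_slope(s) == pytest.approx(-0.005, rel=1e-6)

    def test_flat_spectrum_slope_zero(self):
        assert spectral_slope(flat_spectrum()) == 0.0

    def test_slope_scale_invariance(self, rng):
        s = flat_spectrum()
        s.magnitudes = rng.uniform(0.1, 2.0, 65)
        scaled = FrameSpectrum(s.magnitudes * 7.5, s.bin_freqs_hz, 8.0, FS)
        assert spectral_slope(scaled) == pytest.approx(spectral_slope(s), rel=1e-6)


class TestMfcc:
    def test_mfcc3_is_prefix_of_mfcc13(self, rng):
        frame = rng.normal(size=128)
        v3 = mfcc_features(frame, FS, n_coeffs=3).values
        v13 = mfcc_features(frame, FS, n_coeffs=13).values
        np.testing.assert_array_equal(v3, v13[:3])

    def test_zero_frame_finite(self):
        v = mfcc_features(np.zeros(128), FS, n_coeffs=13).values
        assert np.all(np.isfinite(v))

    def test_gain_leaves_retained_cepstra_unchanged(self, rng):
        frame = 0.1 * rng.normal(size=128)
        a = mfcc_features(frame, FS, n_coeffs=13).values
        b = mfcc_features(frame * 5.0, FS, n_coeffs=13).values
        np.testing.assert_allclose(b, a, atol=1e-6)

    def test_too_short_frame_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            mfcc_features(np.zeros(1), FS)

    def test_bad_coefficient_count_rejected(self):
        with pytest.raises(ValueError, match="3 or 13"):
            mfcc_features(np.zeros(128), FS, n_coeffs=7)


class TestGammatone:
    def test_exactly_14_of_24_centers_above_1khz(self, bank):
        assert bank.center_freqs_hz.size == 24
        assert bank.hi_subset.size == 14

    def test_centers_strictly_increasing(self, bank):
        assert np.all(np.diff(bank.center_freqs_hz) > 0)

    def test_gt14_is_bit_exact_subset_of_gt24(self, bank, rng):
        frame = rng.normal(size=128)
        g24 = gammatone_features(frame, bank, FeatureSet.GT24).values
        g14 = gammatone_features(frame, bank, FeatureSet.GT14).values
        np.testing.assert_array_equal(g14, g24[bank.hi_subset])

    def test_narrowband_excites_nearest_filter(self, bank):
        frame = make_tone_token(4000.0, duration_ms=8.0).samples
        g24 = gammatone_features(frame, bank, FeatureSet.GT24).values
        best = bank.center_freqs_hz[np.argmax(g24)]
        nearest = bank.center_freqs_hz[
            np.argmin(np.abs(bank.center_freqs_hz - 4000.0))
        ]
        assert best == nearest

    def test_fs_mismatch_rejected(self, bank, rng):
        with pytest.raises(ValueError, match="fs"):
            gammatone_features(rng.normal(size=128), bank, FeatureSet.GT24, fs=8000.0)


class TestFftFeatures:
    def test_dimension_is_64(self):
        s = magnitude_spectrum(np.zeros(128), FS)
        assert fft_features(s).values.size == 64

    def test_dc_excluded(self, rng):
        s = magnitude_spectrum(rng.normal(size=128), FS)
        fv = fft_features(s)
        assert "fft_0hz" not in fv.names
        assert fv.names[0] == "fft_125hz"

    def test_dc_only_signal_far_below_dc_bin(self):
        s = magnitude_spectrum(np.full(128, 0.3), FS)
        fv = fft_features(s)
        # the window mainlobe spans ~2 bins; everything beyond it is >50 dB
        # below the DC bin
        dc_db = 20.0 * np.log10(s.magnitudes[0])
        assert np.all(fv.values[2:] < dc_db - 50.0)

    def test_zero_frame_exactly_at_floor(self):
        s = magnitude_spectrum(np.zeros(128), FS)
        fv = fft_features(s)
        np.testing.assert_allclose(fv.values, 20.0 * np.log10(1e-10))

    def test_values_match_magnitude_spectrum(self, rng):
        s = magnitude_spectrum(rng.normal(size=128), FS)
        fv = fft_features(s)
        mask = (s.bin_freqs_hz >= 100.0) & (s.bin_freqs_hz <= 8000.0)
        np.testing.assert_allclose(
            fv.values, 20.0 * np.log10(s.magnitudes[mask] + 1e-10)
        )


class TestDimensions:
    @pytest.mark.parametrize(
        "fset,dim",
        [
            (FeatureSet.M14, 4),
            (FeatureSet.M14PS, 6),
            (FeatureSet.MFCC3, 3),
            (FeatureSet.MFCC13, 13),
            (FeatureSet.GT14, 14),
            (FeatureSet.GT24, 24),
            (FeatureSet.FFTMAG, 64),
        ],
    )
    def test_declared_dimensions(self, fset, dim, bank, rng):
        assert feature_dimension(fset) == dim
        frame = 0.05 * rng.normal(size=128)
        fv = compute_features(frame, FS, fset, bank=bank)
        assert fv.values.size == dim
        assert len(fv.names) == dim
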