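"""8-ms frame cutting and the nine per-frame feature sets.

All features are computed from a single Hamming-windowed frame (8 ms = 128
samples at 16 kHz). Spectral moments, peak and slope are restricted to the
1-8 kHz band of a 128-point FFT; MFCCs come from a 20-filter mel bank on
0-8 kHz; gammatone features are per-filter log-RMS outputs of a 24-filter
ERB-spaced bank on 100-8000 Hz, with the 14 filters above 1 kHz forming the
high-frequency subset.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal
from scipy.fft import dct, rfft, rfftfreq

from .corpus_io import PhoneToken

__all__ = [
    "FrameMode",
    "FeatureSet",
    "FrameSpectrum",
    "FeatureVector",
    "GammatoneBank",
    "SpectralMoments",
    "frame_token",
    "magnitude_spectrum",
    "spectral_moments",
    "spectral_peak",
    "spectral_slope",
    "mfcc_features",
    "gammatone_features",
    "fft_features",
    "make_gammatone_bank",
    "compute_features",
    "feature_dimension",
    "DEFAULT_BAND_HZ",
    "DB_FLOOR",
]

DEFAULT_BAND_HZ = (1000.0, 8000.0)
DB_FLOOR = 1e-10


class FrameMode(enum.Enum):
    RANDOM_ONE = "random_one"  # one seeded random frame (training)
    ALL = "all"  # every non-overlapping frame (testing)


class FeatureSet(enum.Enum):
    M14 = "m14"
    M14PS = "m14ps"
    MFCC3 = "mfcc3"
    MFCC13 = "mfcc13"
    GT14 = "gt14"
    GT24 = "gt24"
    FFTMAG = "fftmag"


@dataclass
class FrameSpectrum:
    """Magnitude spectrum of one windowed frame up to Nyquist."""

    magnitudes: np.ndarray
    bin_freqs_hz: np.ndarray
    frame_ms: float
    fs: float

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=np.float64)
        self.bin_freqs_hz = np.asarray(self.bin_freqs_hz, dtype=np.float64)
        if self.magnitudes.shape != self.bin_freqs_hz.shape:
            raise ValueError("magnitudes and bin_freqs_hz must align")


@dataclass
class FeatureVector:
    feature_set: FeatureSet
    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size != len(self.names):
            raise ValueError("values and names must align")


@dataclass(frozen=True)
class SpectralMoments:
    m1: float  # spectral mean, Hz
    m2: float  # spectral variance, Hz^2
    m3: float  # skewness, unitless
    m4: float  # excess kurtosis, unitless
    degenerate: bool = False  # single active bin: m3/m4 are 0 by convention


def frame_token(
    token: PhoneToken,
    frame_ms: float = 8.0,
    mode: FrameMode = FrameMode.ALL,
    seed: int = 0,
) -> list[np.ndarray]:
    """Cut a token into 8-ms frames.

    ``RANDOM_ONE`` draws one seeded full frame (the training convention);
    ``ALL`` returns every consecutive non-overlapping full frame, dropping a
    partial tail. A token shorter than one frame yields a single zero-padded
    frame in either mode.
    """
    x = np.asarray(token.samples, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot frame an empty token")
    n = int(round(frame_ms * token.fs / 1000.0))
    if n < 16:
        raise ValueError(f"frame of {frame_ms} ms at fs={token.fs} is too short")
    if x.size < n:
        padded = np.zeros(n)
        padded[: x.size] = x
        return [padded]
    if mode is FrameMode.RANDOM_ONE:
        rng = np.random.default_rng(seed)
        start = int(rng.integers(0, x.size - n + 1))
        return [x[start : start + n].copy()]
    n_frames = x.size // n
    return [x[i * n : (i + 1) * n].copy() for i in range(n_frames)]


def magnitude_spectrum(
    frame: np.ndarray, fs: float, nfft: int = 128
) -> FrameSpectrum:
    """Hamming-windowed FFT magnitudes for bins 0..nfft/2."""
    frame = np.asarray(frame, dtype=np.float64)
    if nfft < 2 or nfft & (nfft - 1):
        raise ValueError(f"nfft must be a power of two, got {nfft}")
    if frame.size > nfft:
        raise ValueError(f"frame of {frame.size} samples exceeds nfft={nfft}")
    windowed = frame * np.hamming(frame.size)
    mags = np.abs(rfft(windowed, n=nfft))
    freqs = rfftfreq(nfft, d=1.0 / fs)
    return FrameSpectrum(mags, freqs, frame_ms=1000.0 * frame.size / fs, fs=fs)


def _band_mask(s: FrameSpectrum, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    return (s.bin_freqs_hz >= lo) & (s.bin_freqs_hz <= hi)


def spectral_moments(
    s: FrameSpectrum,
    band: tuple[float, float] = DEFAULT_BAND_HZ,
    mass: str = "power",
) -> SpectralMoments:
    """First four moments of in-band spectral mass over frequency.

    The in-band magnitudes are converted to a probability mass over bin
    frequencies — squared-magnitude power by default (``mass="power"``), or
    floored dB amplitudes shifted to be nonnegative (``mass="db"``, for
    sensitivity checks). Kurtosis is excess (Gaussian -> 0).
    """
    mask = _band_mask(s, band)
    f = s.bin_freqs_hz[mask]
    if f.size < 2:
        raise ValueError("need at least 2 in-band bins")
    if mass == "power":
        w = np.square(s.magnitudes[mask])
    elif mass == "db":
        db = 20.0 * np.log10(s.magnitudes[mask] + DB_FLOOR)
        w = db - db.min()
    else:
        raise ValueError(f"unknown moment mass {mass!r}")
    total = w.sum()
    if total <= 0:
        raise ValueError("all in-band spectral mass is zero")
    p = w / total
    m1 = float(np.dot(f, p))
    d = f - m1
    m2 = float(np.dot(d * d, p))
    if m2 == 0.0:
        return SpectralMoments(m1, 0.0, 0.0, 0.0, degenerate=True)
    m3 = float(np.dot(d**3, p) / m2**1.5)
    m4 = float(np.dot(d**4, p) / m2**2 - 3.0)
    return SpectralMoments(m1, m2, m3, m4)


def spectral_peak(
    s: FrameSpectrum, band: tuple[float, float] = DEFAULT_BAND_HZ
) -> float:
    """Frequency of the largest in-band magnitude (ties -> lowest Hz)."""
    mask = _band_mask(s, band)
    if not mask.any():
        raise ValueError("band contains no FFT bins")
    f = s.bin_freqs_hz[mask]
    return float(f[int(np.argmax(s.magnitudes[mask]))])


def spectral_slope(
    s: FrameSpectrum, band: tuple[float, float] = DEFAULT_BAND_HZ
) -> float:
    """dB amplitude extremes divided by their frequency separation.

    S = (A_max - A_min) / (f_at_max - f_at_min) in dB/Hz; negative when the
    peak lies below the trough in frequency. A flat spectrum (extremes at
    the same bin) returns 0 by convention.
    """
    mask = _band_mask(s, band)
    if not mask.any():
        raise ValueError("band contains no FFT bins")
    f = s.bin_freqs_hz[mask]
    amp_db = 20.0 * np.log10(s.magnitudes[mask] + DB_FLOOR)
    i_max = int(np.argmax(amp_db))
    i_min = int(np.argmin(amp_db))
    if i_max == i_min or f[i_max] == f[i_min]:
        return 0.0
    return float((amp_db[i_max] - amp_db[i_min]) / (f[i_max] - f[i_min]))


# ---------------------------------------------------------------------------
# MFCC front-end

def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


@lru_cache(maxsize=8)
def _mel_filterbank(fs: float, nfft: int, n_filters: int, f_lo: float, f_hi: float):
    """Triangular mel filterbank over rfft bins (rows sum the power spectrum)."""
    edges_hz = _mel_to_hz(
        np.linspace(_hz_to_mel(f_lo), _hz_to_mel(f_hi), n_filters + 2)
    )
    freqs = rfftfreq(nfft, d=1.0 / fs)
    bank = np.zeros((n_filters, freqs.size))
    for i in range(n_filters):
        lo, mid, hi = edges_hz[i], edges_hz[i + 1], edges_hz[i + 2]
        rising = (freqs - lo) / max(mid - lo, 1e-12)
        falling = (hi - freqs) / max(hi - mid, 1e-12)
        bank[i] = np.clip(np.minimum(rising, falling), 0.0, None)
    return bank


def mfcc_features(
    frame: np.ndarray,
    fs: float,
    n_coeffs: int = 13,
    nfft: int = 128,
    n_filters: int = 20,
) -> FeatureVector:
    """Mel-cepstral coefficients 1..n of one frame (no deltas, no 0th).

    The 3-coefficient variant is bit-identical to the first three entries of
    the 13-coefficient one. Scaling the frame by a positive gain shifts only
    the excluded 0th (energy) cepstrum, leaving these coefficients fixed.
    """
    if n_coeffs not in (3, 13):
        raise ValueError("n_coeffs must be 3 or 13")
    frame = np.asarray(frame, dtype=np.float64)
    if frame.size < 2:
        raise ValueError("frame must have at least 2 samples")
    spec = magnitude_spectrum(frame, fs, nfft=nfft)
    power = np.square(spec.magnitudes)
    bank = _mel_filterbank(float(fs), nfft, n_filters, 0.0, fs / 2.0)
    log_energies = np.log(bank @ power + DB_FLOOR)
    cepstra = dct(log_energies, type=2, norm="ortho")
    values = cepstra[1 : n_coeffs + 1]
    fset = FeatureSet.MFCC3 if n_coeffs == 3 else FeatureSet.MFCC13
    return FeatureVector(fset, values, [f"mfcc{i}" for i in range(1, n_coeffs + 1)])


# ---------------------------------------------------------------------------
# Gammatone front-end

def _erb_rate(f):
    """Glasberg & Moore ERB-rate scale."""
    return 21.4 * np.log10(4.37 * np.asarray(f, dtype=np.float64) / 1000.0 + 1.0)


def _erb_rate_inv(r):
    return (10.0 ** (np.asarray(r, dtype=np.float64) / 21.4) - 1.0) * 1000.0 / 4.37


@dataclass
class GammatoneBank:
    """ERB-rate-spaced bank of 4th-order gammatone IIR filters."""

    center_freqs_hz: np.ndarray
    fs: float
    order: int = 4
    hi_cut_hz: float = 1000.0
    _filters: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    @property
    def hi_subset(self) -> np.ndarray:
        """Indices of the filters centered above ``hi_cut_hz``."""
        return np.flatnonzero(self.center_freqs_hz > self.hi_cut_hz)


def make_gammatone_bank(
    fs: float = 16000.0,
    n_filters: int = 24,
    f_lo: float = 100.0,
    f_hi: float = 8000.0,
) -> GammatoneBank:
    """Design ``n_filters`` gammatone filters ERB-spaced on [f_lo, f_hi].

    Centers at or above Nyquist are clamped just below it for the IIR
    design (the nominal top edge of 8 kHz coincides with Nyquist at 16 kHz).
    """
    if f_lo <= 0 or f_hi <= f_lo:
        raise ValueError("need 0 < f_lo < f_hi")
    centers = _erb_rate_inv(np.linspace(_erb_rate(f_lo), _erb_rate(f_hi), n_filters))
    centers = np.minimum(centers, fs / 2.0 * (1.0 - 1e-3))
    bank = GammatoneBank(centers, fs)
    for cf in centers:
        b, a = signal.gammatone(cf, "iir", fs=fs)
        bank._filters.append((b, a))
    return bank


def gammatone_features(
    frame: np.ndarray,
    bank: GammatoneBank,
    subset: FeatureSet = FeatureSet.GT24,
    fs: float | None = None,
) -> FeatureVector:
    """Per-filter log-RMS of the gammatone-filtered frame.

    The 14-filter variant is the 24-filter vector restricted to the centers
    above 1 kHz (bit-exact subset, not a separate computation).
    """
    if fs is not None and fs != bank.fs:
        raise ValueError(f"frame fs {fs} != bank fs {bank.fs}")
    frame = np.asarray(frame, dtype=np.float64)
    values = np.empty(bank.center_freqs_hz.size)
    for i, (b, a) in enumerate(bank._filters):
        y = signal.lfilter(b, a, frame)
        values[i] = np.log(np.sqrt(np.mean(np.square(y))) + DB_FLOOR)
    names = [f"gt_{cf:.0f}hz" for cf in bank.center_freqs_hz]
    if subset is FeatureSet.GT24:
        return FeatureVector(FeatureSet.GT24, values, names)
    if subset is FeatureSet.GT14:
        idx = bank.hi_subset
        return FeatureVector(FeatureSet.GT14, values[idx], [names[i] for i in idx])
    raise ValueError(f"subset must be GT24 or GT14, got {subset}")


def fft_features(
    s: FrameSpectrum, band: tuple[float, float] = (100.0, 8000.0)
) -> FeatureVector:
    """Floored dB magnitudes of every bin in [100, 8000] Hz (DC excluded)."""
    mask = _band_mask(s, band)
    f = s.bin_freqs_hz[mask]
    values = 20.0 * np.log10(s.magnitudes[mask] + DB_FLOOR)
    return FeatureVector(
        FeatureSet.FFTMAG, values, [f"fft_{fi:.0f}hz" for fi in f]
    )


# ---------------------------------------------------------------------------
# Dispatcher

def compute_features(
    frame: np.ndarray,
    fs: float,
    feature_set: FeatureSet,
    bank: GammatoneBank | None = None,
    nfft: int = 128,
) -> FeatureVector:
    """Compute one named feature set for one frame."""
    if feature_set in (FeatureSet.GT14, FeatureSet.GT24):
        if bank is None:
            bank = make_gammatone_bank(fs=fs)
        return gammatone_features(frame, bank, subset=feature_set, fs=fs)
    if feature_set is FeatureSet.MFCC3:
        return mfcc_features(frame, fs, n_coeffs=3, nfft=nfft)
    if feature_set is FeatureSet.MFCC13:
        return mfcc_features(frame, fs, n_coeffs=13, nfft=nfft)
    s = magnitude_spectrum(frame, fs, nfft=nfft)
    if feature_set is FeatureSet.FFTMAG:
        return fft_features(s)
    mom = spectral_moments(s)
    if feature_set is FeatureSet.M14:
        return FeatureVector(
            FeatureSet.M14,
            [mom.m1, mom.m2, mom.m3, mom.m4],
            ["m1", "m2", "m3", "m4"],
        )
    if feature_set is FeatureSet.M14PS:
        return FeatureVector(
            FeatureSet.M14PS,
            [mom.m1, mom.m2, mom.m3, mom.m4, spectral_peak(s), spectral_slope(s)],
            ["m1", "m2", "m3", "m4", "peak", "slope"],
        )
    raise ValueError(f"unknown feature set {feature_set}")


def feature_dimension(
    feature_set: FeatureSet, fs: float = 16000.0, nfft: int = 128
) -> int:
    """Declared dimensionality of each feature set."""
    fixed = {
        FeatureSet.M14: 4,
        FeatureSet.M14PS: 6,
        FeatureSet.MFCC3: 3,
        FeatureSet.MFCC13: 13,
        FeatureSet.GT14: 14,
        FeatureSet.GT24: 24,
    }
    if feature_set in fixed:
        return fixed[feature_set]
    freqs = rfftfreq(nfft, d=1.0 / fs)
    return int(np.count_nonzero((freqs >= 100.0) & (freqs <= 8000.0)))
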