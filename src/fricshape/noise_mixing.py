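"""Masker synthesis (speech-shaped noise, multi-talker babble) and SNR mixing.

Speech-shaped noise (SSN) is white Gaussian noise lowpass-filtered by a
first-order Butterworth at 800 Hz, approximating the long-term average
speech spectrum. Babble is a sum of independent speech-like streams; when no
talker recordings are supplied, each stream is SSN amplitude-modulated by a
slow (2-8 Hz) random envelope, which mimics syllabic rate fluctuations.

The filter runs single-pass by default so the noise power spectrum follows
the first-order magnitude response exactly (-3 dB at the cutoff, -6
dB/octave asymptotically); set ``zero_phase=True`` for a forward-backward
pass if phase linearity matters more than the spectral contract.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .corpus_io import DEFAULT_TARGET_RMS, Utterance, rms, rms_equalize

__all__ = [
    "NoiseKind",
    "NoiseSpec",
    "generate_ssn",
    "synthesize_babble",
    "mix_at_snr",
    "TRAIN_SSN_SNR_DB",
    "TEST_BABBLE_SNRS_DB",
]

#: Training-time masker level: SSN at +10 dB SNR.
TRAIN_SSN_SNR_DB = 10.0

#: Test-time babble SNR sweep, mismatched with the training masker.
TEST_BABBLE_SNRS_DB = (20.0, 15.0, 10.0, 5.0, 0.0, -5.0, -10.0)


class NoiseKind(enum.Enum):
    SSN = "ssn"
    BABBLE = "babble"


@dataclass
class NoiseSpec:
    """Parameters of a masker generator."""

    kind: NoiseKind
    fs: float = 16000.0
    cutoff_hz: float = 800.0
    n_talkers: int = 12
    seed: int = 0
    target_rms: float = DEFAULT_TARGET_RMS
    zero_phase: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.kind, str):
            self.kind = NoiseKind(self.kind)
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff_hz must be positive")
        if self.kind is NoiseKind.BABBLE and self.n_talkers < 1:
            raise ValueError("n_talkers must be >= 1")


def _ssn_samples(
    n: int, fs: float, cutoff_hz: float, rng: np.random.Generator, zero_phase: bool
) -> np.ndarray:
    if cutoff_hz >= fs / 2:
        raise ValueError(
            f"SSN cutoff {cutoff_hz} Hz must lie below Nyquist ({fs / 2} Hz)"
        )
    white = rng.standard_normal(n)
    b, a = signal.butter(1, cutoff_hz, btype="low", fs=fs)
    if zero_phase:
        return signal.filtfilt(b, a, white)
    return signal.lfilter(b, a, white)


def generate_ssn(duration_s: float, spec: NoiseSpec) -> Utterance:
    """Seeded speech-shaped noise of the requested duration."""
    if spec.kind is not NoiseKind.SSN:
        raise ValueError("spec.kind must be SSN")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = int(round(duration_s * spec.fs))
    rng = np.random.default_rng(spec.seed)
    x = _ssn_samples(n, spec.fs, spec.cutoff_hz, rng, spec.zero_phase)
    return rms_equalize(
        Utterance(f"ssn_seed{spec.seed}", x, spec.fs), spec.target_rms
    )


def _modulated_stream(
    n: int, fs: float, cutoff_hz: float, rng: np.random.Generator, zero_phase: bool
) -> np.ndarray:
    """One synthetic talker: SSN carrier with a slow random envelope."""
    carrier = _ssn_samples(n, fs, cutoff_hz, rng, zero_phase)
    rate_hz = rng.uniform(2.0, 8.0)
    # slow modulator from interpolated Gaussian knots at the syllabic rate
    # (an IIR lowpass at a few Hz against fs is numerically unreliable)
    n_knots = max(4, int(np.ceil(rate_hz * n / fs)) + 2)
    knots = rng.standard_normal(n_knots)
    t = np.arange(n) / fs
    slow = np.interp(t, np.linspace(0.0, n / fs, n_knots), knots)
    sd = np.std(slow)
    if sd > 0:
        slow = slow / sd
    envelope = np.maximum(0.0, 1.0 + 0.8 * slow)
    return carrier * envelope


def synthesize_babble(
    duration_s: float,
    spec: NoiseSpec,
    talker_bank: Sequence[Utterance] | None = None,
) -> Utterance:
    """Multi-talker babble: a sum of independent speech-like streams.

    With ``talker_bank`` given, streams are random contiguous excerpts of the
    supplied recordings (each must cover the requested duration); otherwise
    synthetic modulated-SSN streams are used.
    """
    if spec.kind is not NoiseKind.BABBLE:
        raise ValueError("spec.kind must be BABBLE")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = int(round(duration_s * spec.fs))
    streams = np.zeros(n)
    child_seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_talkers)
    for k in range(spec.n_talkers):
        rng = np.random.default_rng(child_seeds[k])
        if talker_bank is None:
            streams += _modulated_stream(
                n, spec.fs, spec.cutoff_hz, rng, spec.zero_phase
            )
        else:
            source = talker_bank[k % len(talker_bank)]
            if source.samples.size < n:
                raise ValueError(
                    f"talker recording {source.id!r} is shorter than the "
                    f"requested babble duration"
                )
            start = int(rng.integers(0, source.samples.size - n + 1))
            streams += source.samples[start : start + n]
    return rms_equalize(
        Utterance(f"babble_seed{spec.seed}", streams, spec.fs), spec.target_rms
    )


def mix_at_snr(
    speech: Utterance, masker: Utterance, snr_db: float, seed: int = 0
) -> Utterance:
    """Add a random masker segment to speech at an exact RMS-ratio SNR.

    A contiguous masker segment of matching length is drawn with ``seed``
    and scaled so 20*log10(rms(speech)/rms(segment)) equals ``snr_db``.
    """
    if masker.fs != speech.fs:
        raise ValueError("speech and masker sampling rates differ")
    n = speech.samples.size
    if masker.samples.size < n:
        raise ValueError("masker must be at least as long as the speech")
    speech_rms = rms(speech.samples)
    if speech_rms == 0.0:
        raise ValueError("speech has zero RMS")
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, masker.samples.size - n + 1))
    segment = masker.samples[start : start + n]
    seg_rms = rms(segment)
    if seg_rms == 0.0:
        raise ValueError("drawn masker segment has zero RMS")
    gain = speech_rms / (seg_rms * 10.0 ** (snr_db / 20.0))
    return Utterance(
        f"{speech.id}+{masker.id}@{snr_db:+g}dB",
        speech.samples + gain * segment,
        speech.fs,
    )
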