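"""Synthetic labeled fricative corpora for pipeline testing and calibration.

Tokens are stationary shaped noise: white noise spectrally shaped by a
single second-order resonance plus a linear spectral tilt in dB, with a
low-frequency component added for voiced phones. Default class envelopes
put the dominant spectral peak near 1750 Hz (non-sibilant), 4625 Hz
(alveolar) and 3250 Hz (palatal), and give the in-band spectral slope the
sign pattern (-, +, -) across the three groups. Talker variability is a
multiplicative (log-normal) shift of the peak frequency, mimicking
vocal-tract scaling; train/test splits are talker-disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.fft import irfft, rfft, rfftfreq

from .corpus_io import (
    DEFAULT_TARGET_RMS,
    FricativeGroup,
    PhoneSegment,
    PhoneToken,
    Utterance,
    rms_equalize,
    write_phone_labels,
    write_wav,
)

__all__ = [
    "ClassEnvelopeSpec",
    "CorpusSpec",
    "default_specs",
    "generate_token",
    "generate_corpus",
    "write_corpus",
]

GROUP_PHONES = {
    FricativeGroup.NONSIB: ("f", "th", "v", "dh"),
    FricativeGroup.ALV: ("s", "z"),
    FricativeGroup.PAL: ("sh", "zh"),
}
VOICED_PHONES = frozenset({"v", "dh", "z", "zh"})


@dataclass
class ClassEnvelopeSpec:
    """Spectral envelope family of one fricative group."""

    group: FricativeGroup
    peak_hz_median: float
    peak_hz_spread: float = 150.0  # per-token jitter std, Hz
    bandwidth_hz: float = 1000.0
    tilt_db_per_khz: float = 0.0
    level_db_spread: float = 3.0

    def __post_init__(self) -> None:
        if self.peak_hz_median <= 0 or self.bandwidth_hz <= 0:
            raise ValueError("peak and bandwidth must be positive")
        if self.peak_hz_spread < 0 or self.level_db_spread < 0:
            raise ValueError("spreads must be nonnegative")


def default_specs(spread_scale: float = 1.0) -> dict[FricativeGroup, ClassEnvelopeSpec]:
    """Default per-group envelopes; ``spread_scale`` is a difficulty dial
    multiplying every within-class variability parameter."""
    specs = {
        FricativeGroup.NONSIB: ClassEnvelopeSpec(
            FricativeGroup.NONSIB,
            peak_hz_median=1750.0,
            peak_hz_spread=150.0,
            bandwidth_hz=600.0,
            tilt_db_per_khz=-3.0,
        ),
        FricativeGroup.ALV: ClassEnvelopeSpec(
            FricativeGroup.ALV,
            peak_hz_median=4625.0,
            peak_hz_spread=250.0,
            bandwidth_hz=1600.0,
            tilt_db_per_khz=1.0,
        ),
        FricativeGroup.PAL: ClassEnvelopeSpec(
            FricativeGroup.PAL,
            peak_hz_median=3250.0,
            peak_hz_spread=200.0,
            bandwidth_hz=700.0,
            tilt_db_per_khz=-1.5,
        ),
    }
    for s in specs.values():
        s.peak_hz_spread *= spread_scale
        s.level_db_spread *= spread_scale
    return specs


@dataclass
class CorpusSpec:
    """Shape and reproducibility parameters of a generated corpus."""

    n_tokens_per_group: int = 100
    duration_ms_range: tuple[float, float] = (30.0, 150.0)
    fs: float = 16000.0
    n_talkers: int = 10
    talker_spread: float = 0.05  # log-std of the talker peak-scaling factor
    seed: int = 0
    n_train_talkers: int | None = None  # default: 80% of talkers

    def __post_init__(self) -> None:
        lo, hi = self.duration_ms_range
        if lo < 8.0 or hi < lo:
            raise ValueError("durations must cover at least one 8-ms frame")
        if self.n_talkers < 2:
            raise ValueError("need at least 2 talkers for a disjoint split")
        n_train = self.resolved_train_talkers
        if not 0 < n_train < self.n_talkers:
            raise ValueError("talker split leaves an empty train or test set")

    @property
    def resolved_train_talkers(self) -> int:
        if self.n_train_talkers is not None:
            return self.n_train_talkers
        return max(1, int(round(0.8 * self.n_talkers)))


def _envelope(
    f: np.ndarray, peak_hz: float, bandwidth_hz: float, tilt_db_per_khz: float,
    voiced: bool,
) -> np.ndarray:
    q = peak_hz / bandwidth_hz
    ratio = f / peak_hz
    resonance = 1.0 / np.sqrt(
        np.square(1.0 - np.square(ratio)) + np.square(ratio / q)
    )
    tilt = 10.0 ** (tilt_db_per_khz * f / 1000.0 / 20.0)
    h = resonance * tilt
    if voiced:
        # voiced fricatives carry extra energy below ~1 kHz
        h = h * (1.0 + 3.0 * np.exp(-np.square(f / 350.0)))
    return h


def _calibrated_resonance_hz(
    target_peak_hz: float,
    bandwidth_hz: float,
    tilt_db_per_khz: float,
    voiced: bool,
    fs: float,
) -> float:
    """Resonance frequency whose full envelope peaks at ``target_peak_hz``.

    The tilt (and the voiced low-frequency component) shift the envelope
    argmax away from the bare resonance, so the resonance is placed by a
    short bisection on the monotone argmax-vs-resonance relation.
    """
    grid = np.linspace(50.0, fs / 2.0, 2048)

    def measured_peak(fp: float) -> float:
        return float(grid[np.argmax(_envelope(grid, fp, bandwidth_hz,
                                              tilt_db_per_khz, voiced))])

    lo, hi = target_peak_hz * 0.5, min(target_peak_hz * 2.0, fs / 2.0 * 0.999)
    if measured_peak(lo) >= target_peak_hz or measured_peak(hi) <= target_peak_hz:
        return target_peak_hz  # degenerate envelope; fall back to the bare value
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if measured_peak(mid) < target_peak_hz:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_token(
    spec: ClassEnvelopeSpec,
    talker_factor: float,
    duration_ms: float,
    fs: float,
    seed: int,
    phone: str | None = None,
    utterance_id: str = "synth",
    target_rms: float = DEFAULT_TARGET_RMS,
) -> PhoneToken:
    """One stationary shaped-noise token of the given class.

    The realized peak is the class median scaled by the talker factor plus
    per-token Gaussian jitter; the token level gets a dB jitter around the
    corpus reference RMS. Identical arguments reproduce the waveform
    bit-exactly.
    """
    if duration_ms < 8.0:
        raise ValueError("token must cover at least one 8-ms frame")
    rng = np.random.default_rng(seed)
    if phone is None:
        phone = str(rng.choice(GROUP_PHONES[spec.group]))
    base_peak = spec.peak_hz_median * talker_factor
    if not 0 < base_peak < fs / 2:
        raise ValueError(f"class peak {base_peak:.0f} Hz is outside (0, Nyquist)")
    # per-token jitter is clipped into the valid band so large difficulty
    # settings cannot push a rare Gaussian tail draw past Nyquist
    peak_hz = float(
        np.clip(
            base_peak + rng.normal(0.0, spec.peak_hz_spread),
            100.0,
            0.97 * fs / 2.0,
        )
    )
    voiced = phone in VOICED_PHONES
    resonance_hz = _calibrated_resonance_hz(
        peak_hz, spec.bandwidth_hz, spec.tilt_db_per_khz, voiced, fs
    )
    n = int(round(duration_ms * fs / 1000.0))
    white = rng.standard_normal(n)
    spectrum = rfft(white)
    f = rfftfreq(n, d=1.0 / fs)
    shaped = irfft(
        spectrum
        * _envelope(f, resonance_hz, spec.bandwidth_hz, spec.tilt_db_per_khz, voiced),
        n=n,
    )
    level = target_rms * 10.0 ** (rng.normal(0.0, spec.level_db_spread) / 20.0)
    samples = rms_equalize(Utterance(utterance_id, shaped, fs), level).samples
    return PhoneToken(
        utterance_id=utterance_id,
        group=spec.group,
        samples=samples,
        fs=fs,
        phone=phone,
    )


def generate_corpus(
    specs: dict[FricativeGroup, ClassEnvelopeSpec] | None = None,
    cs: CorpusSpec | None = None,
) -> tuple[list[PhoneToken], list[PhoneToken], pd.DataFrame]:
    """Balanced talker-disjoint train/test token sets plus a manifest.

    Each split gets ``n_tokens_per_group`` tokens per group. The manifest
    records every per-token seed and parameter needed for bit-exact
    regeneration.
    """
    specs = specs or default_specs()
    cs = cs or CorpusSpec()
    root = np.random.SeedSequence(cs.seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    factors = np.exp(rng.normal(0.0, cs.talker_spread, size=cs.n_talkers))
    talker_ids = rng.permutation(cs.n_talkers)
    n_train = cs.resolved_train_talkers
    split_talkers = {
        "train": talker_ids[:n_train],
        "test": talker_ids[n_train:],
    }
    token_seeds = iter(root.spawn(2 * 3 * cs.n_tokens_per_group))
    out: dict[str, list[PhoneToken]] = {"train": [], "test": []}
    records = []
    lo, hi = cs.duration_ms_range
    for split in ("train", "test"):
        for group in FricativeGroup:
            for i in range(cs.n_tokens_per_group):
                ss = next(token_seeds)
                draw = np.random.default_rng(ss)
                talker = int(draw.choice(split_talkers[split]))
                duration_ms = float(draw.uniform(lo, hi))
                token_seed = int(ss.generate_state(1)[0])
                uid = f"{split}_t{talker:02d}_{group.name.lower()}_{i:04d}"
                token = generate_token(
                    specs[group],
                    talker_factor=float(factors[talker]),
                    duration_ms=duration_ms,
                    fs=cs.fs,
                    seed=token_seed,
                    utterance_id=uid,
                )
                out[split].append(token)
                records.append(
                    {
                        "utterance_id": uid,
                        "split": split,
                        "group": group.name,
                        "phone": token.phone,
                        "talker": talker,
                        "talker_factor": float(factors[talker]),
                        "duration_ms": duration_ms,
                        "seed": token_seed,
                        "fs": cs.fs,
                    }
                )
    return out["train"], out["test"], pd.DataFrame(records)


def write_corpus(
    out_dir: str | Path,
    train: list[PhoneToken],
    test: list[PhoneToken],
    manifest: pd.DataFrame,
) -> None:
    """Write WAV + ``.phn`` per token plus the CSV manifest, so generated
    corpora flow through the regular corpus readers unchanged."""
    out_dir = Path(out_dir)
    for split, tokens in (("train", train), ("test", test)):
        d = out_dir / split
        d.mkdir(parents=True, exist_ok=True)
        for t in tokens:
            write_wav(d / f"{t.utterance_id}.wav", Utterance(t.utterance_id, t.samples, t.fs))
            write_phone_labels(
                d / f"{t.utterance_id}.phn",
                [PhoneSegment(0, t.samples.size, t.phone)],
            )
    manifest.to_csv(out_dir / "manifest.csv", index=False)
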