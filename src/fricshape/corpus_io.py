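"""WAV / phone-label I/O, level equalization, and fricative token extraction.

Phone label files follow the TIMIT ``.phn`` dialect: one segment per line,
``<start_sample> <end_sample> <label>`` with 0-based, end-exclusive sample
indices. Phones are ARPAbet-style ASCII (``th`` for the interdental
voiceless fricative, ``sh`` for the palatal one, and so on).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "FricativeGroup",
    "PHONE_GROUP_MAP",
    "Utterance",
    "PhoneSegment",
    "PhoneToken",
    "read_wav",
    "write_wav",
    "read_phone_labels",
    "write_phone_labels",
    "rms",
    "rms_equalize",
    "phone_to_group",
    "extract_fricative_tokens",
    "tokens_to_manifest",
    "DEFAULT_TARGET_RMS",
]

#: Default full-scale RMS used when equalizing sentence levels.
DEFAULT_TARGET_RMS = 0.05


class FricativeGroup(enum.IntEnum):
    """Place-of-articulation group of an obstruent fricative."""

    NONSIB = 0  # labiodental + interdental: f, v, th, dh
    ALV = 1  # alveolar: s, z
    PAL = 2  # palatal: sh, zh


#: Mapping from ARPAbet fricative phones to their class group.  /h/ (``hh``)
#: is deliberately absent: it is not produced with an oral constriction and
#: is never classified.
PHONE_GROUP_MAP: Mapping[str, FricativeGroup] = {
    "f": FricativeGroup.NONSIB,
    "v": FricativeGroup.NONSIB,
    "th": FricativeGroup.NONSIB,
    "dh": FricativeGroup.NONSIB,
    "s": FricativeGroup.ALV,
    "z": FricativeGroup.ALV,
    "sh": FricativeGroup.PAL,
    "zh": FricativeGroup.PAL,
}


@dataclass
class Utterance:
    """A mono audio signal with full-scale float samples in [-1, 1]."""

    id: str
    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class PhoneSegment:
    """One labeled span of an utterance (0-based, end-exclusive samples)."""

    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid segment span [{self.start}, {self.end})"
            )
        if not self.label:
            raise ValueError("segment label must be non-empty")


@dataclass
class PhoneToken:
    """A labeled fricative segment extracted from an utterance."""

    utterance_id: str
    group: FricativeGroup
    samples: np.ndarray
    fs: float
    phone: str
    start: int = 0
    end: int = field(default=0)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.end == 0:
            self.end = self.start + self.samples.size
        if self.samples.size != self.end - self.start:
            raise ValueError("token length must equal its segment span")


def read_wav(path: str | Path, utterance_id: str | None = None) -> Utterance:
    """Read a mono PCM or float WAV file into a full-scale Utterance."""
    fs, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got shape {data.shape}")
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        samples = data.astype(np.float64)
    uid = utterance_id if utterance_id is not None else Path(path).stem
    return Utterance(uid, samples, float(fs))


def write_wav(path: str | Path, u: Utterance, dtype: str = "int16") -> None:
    """Write an Utterance as PCM-16 (default) or float32 WAV."""
    if dtype == "int16":
        clipped = np.clip(u.samples, -1.0, 32767.0 / 32768.0)
        data = np.round(clipped * 32768.0).astype(np.int16)
    elif dtype == "float32":
        data = u.samples.astype(np.float32)
    else:
        raise ValueError(f"unsupported WAV dtype {dtype!r}")
    wavfile.write(str(path), int(u.fs), data)


def read_phone_labels(path: str | Path) -> list[PhoneSegment]:
    """Parse a TIMIT-style ``.phn`` file into segments, in file order."""
    segments: list[PhoneSegment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 'start end label', got {line!r}"
                )
            try:
                start, end = int(fields[0]), int(fields[1])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer boundary in {line!r}"
                ) from exc
            if end <= start:
                raise ValueError(
                    f"{path}:{lineno}: end {end} <= start {start}"
                )
            segments.append(PhoneSegment(start, end, fields[2]))
    return segments


def write_phone_labels(path: str | Path, segments: Iterable[PhoneSegment]) -> None:
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f"{seg.start} {seg.end} {seg.label}\n")


def rms(x: np.ndarray) -> float:
    """Root-mean-square amplitude."""
    x = np.asarray(x, dtype=np.float64)
    return float(np.sqrt(np.mean(np.square(x))))


def rms_equalize(u: Utterance, target_rms: float = DEFAULT_TARGET_RMS) -> Utterance:
    """Scale an utterance so its RMS equals ``target_rms`` exactly.

    The waveform shape is preserved (pure scalar gain). Raises on silence,
    which cannot be scaled to a nonzero level.
    """
    if target_rms <= 0:
        raise ValueError("target_rms must be positive")
    level = rms(u.samples)
    if level == 0.0:
        raise ValueError(f"utterance {u.id!r} is all-zero; cannot equalize")
    return Utterance(u.id, u.samples * (target_rms / level), u.fs)


def phone_to_group(phone: str) -> FricativeGroup:
    """Map a fricative phone to its group; raises for unmapped phones."""
    try:
        return PHONE_GROUP_MAP[phone]
    except KeyError:
        raise KeyError(
            f"phone {phone!r} is not one of the eight classified fricatives"
        ) from None


def extract_fricative_tokens(
    u: Utterance,
    segments: Sequence[PhoneSegment],
    phone_map: Mapping[str, FricativeGroup] = PHONE_GROUP_MAP,
) -> list[PhoneToken]:
    """Cut out the segments whose label is a mapped fricative phone.

    Non-fricative labels are silently skipped (they are ordinary phones, not
    errors). A segment extending past the end of the signal is an error.
    """
    tokens: list[PhoneToken] = []
    for seg in segments:
        if seg.label not in phone_map:
            continue
        if seg.end > u.samples.size:
            raise ValueError(
                f"segment [{seg.start}, {seg.end}) exceeds utterance "
                f"{u.id!r} of length {u.samples.size}"
            )
        tokens.append(
            PhoneToken(
                utterance_id=u.id,
                group=phone_map[seg.label],
                samples=u.samples[seg.start : seg.end].copy(),
                fs=u.fs,
                phone=seg.label,
                start=seg.start,
                end=seg.end,
            )
        )
    return tokens


def tokens_to_manifest(tokens: Sequence[PhoneToken]) -> pd.DataFrame:
    """Token bookkeeping as a DataFrame (CSV-friendly)."""
    return pd.DataFrame(
        {
            "utterance_id": [t.utterance_id for t in tokens],
            "phone": [t.phone for t in tokens],
            "group": [t.group.name for t in tokens],
            "start": [t.start for t in tokens],
            "end": [t.end for t in tokens],
        }
    )
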