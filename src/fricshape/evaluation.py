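"""Scoring: accuracy, confusion matrices, feature screening, CI widths."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus_io import FricativeGroup, PhoneToken
from .frame_features import (
    FrameMode,
    frame_token,
    magnitude_spectrum,
    spectral_moments,
    spectral_peak,
    spectral_slope,
)

__all__ = [
    "ConfusionMatrix",
    "score_run",
    "kruskal_wallis",
    "bernoulli_ci_width",
    "feature_screening_report",
]

GROUP_NAMES = [g.name for g in FricativeGroup]


@dataclass
class ConfusionMatrix:
    """Counts (rows = true, cols = detected) plus row-normalized percents."""

    counts: np.ndarray
    row_percent: np.ndarray
    empty_rows: tuple[int, ...] = ()  # classes absent from the truth

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    def to_frame(self, percent: bool = True) -> pd.DataFrame:
        data = self.row_percent if percent else self.counts
        return pd.DataFrame(
            data,
            index=[f"true_{n}" for n in GROUP_NAMES],
            columns=[f"detected_{n}" for n in GROUP_NAMES],
        )


def score_run(
    true_groups: Sequence[FricativeGroup | int],
    predicted_groups: Sequence[FricativeGroup | int],
) -> tuple[float, ConfusionMatrix]:
    """Overall accuracy (proportion correct) and the confusion matrix."""
    t = np.asarray([int(g) for g in true_groups])
    p = np.asarray([int(g) for g in predicted_groups])
    if t.size == 0 or t.size != p.size:
        raise ValueError("true and predicted label sequences must match and be non-empty")
    n = len(FricativeGroup)
    counts = np.zeros((n, n), dtype=int)
    np.add.at(counts, (t, p), 1)
    row_sums = counts.sum(axis=1)
    row_percent = np.zeros((n, n))
    empty = tuple(int(i) for i in np.flatnonzero(row_sums == 0))
    nz = row_sums > 0
    row_percent[nz] = 100.0 * counts[nz] / row_sums[nz, None]
    cm = ConfusionMatrix(counts, row_percent, empty_rows=empty)
    return cm.accuracy, cm


def kruskal_wallis(*groups: Sequence[float]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) with the chi-square p approximation.

    The degenerate all-identical case returns (0, 1) instead of failing.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group needs at least one value")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def bernoulli_ci_width(p: float, n: int) -> float:
    """Width (percentage points) of the normal-approximation 95% CI.

    width = 100 * 2 * 1.96 * sqrt(p * (1 - p) / n).
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly between 0 and 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    return 100.0 * 2.0 * 1.96 * float(np.sqrt(p * (1.0 - p) / n))


def feature_screening_report(
    tokens: Sequence[PhoneToken],
    seed: int = 0,
    frame_ms: float = 8.0,
) -> pd.DataFrame:
    """Per-group medians of the six spectral features, with Kruskal-Wallis p.

    Each token contributes one randomly chosen 8-ms frame. Rows are the six
    features (M1, M2, M3, M4, P, S); columns are the group medians plus the
    p-value of the across-group Kruskal-Wallis test.
    """
    present = {t.group for t in tokens}
    missing = [g.name for g in FricativeGroup if g not in present]
    if missing:
        raise ValueError(f"groups missing from the token set: {missing}")
    seeds = np.random.SeedSequence(seed).spawn(len(tokens))
    per_group: dict[FricativeGroup, dict[str, list[float]]] = {
        g: {k: [] for k in ("M1", "M2", "M3", "M4", "P", "S")}
        for g in FricativeGroup
    }
    for token, ss in zip(tokens, seeds):
        frame = frame_token(
            token, frame_ms=frame_ms, mode=FrameMode.RANDOM_ONE,
            seed=int(ss.generate_state(1)[0]),
        )[0]
        s = magnitude_spectrum(frame, token.fs)
        mom = spectral_moments(s)
        vals = per_group[token.group]
        vals["M1"].append(mom.m1)
        vals["M2"].append(mom.m2)
        vals["M3"].append(mom.m3)
        vals["M4"].append(mom.m4)
        vals["P"].append(spectral_peak(s))
        vals["S"].append(spectral_slope(s))
    rows = []
    for feat in ("M1", "M2", "M3", "M4", "P", "S"):
        samples = [per_group[g][feat] for g in FricativeGroup]
        _, p = kruskal_wallis(*samples)
        rows.append(
            {
                "feature": feat,
                **{
                    f"median_{g.name}": float(np.median(per_group[g][feat]))
                    for g in FricativeGroup
                },
                "p_value": p,
            }
        )
    return pd.DataFrame(rows).set_index("feature")
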