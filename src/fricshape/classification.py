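"""3-class RBF SVM training with grid-search CV and majority-vote decoding.

Training draws one random 8-ms frame from the clean version of each token
and one from its SSN-corrupted version (+10 dB SNR by default). Features
are z-scored with statistics fit on training rows only; (C, gamma) are
picked by seeded stratified k-fold cross-validation with deterministic tie
breaking (smallest C, then smallest gamma). At test time every
non-overlapping 8-ms frame of a token is labeled and the token gets the
modal frame label; vote ties fall back to the largest summed one-vs-one
decision margin, then the lowest class index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .corpus_io import FricativeGroup, PhoneToken, Utterance
from .dimred import ProjectionModel, project
from .frame_features import (
    FeatureSet,
    FrameMode,
    GammatoneBank,
    compute_features,
    frame_token,
    make_gammatone_bank,
)
from .noise_mixing import TRAIN_SSN_SNR_DB, mix_at_snr

__all__ = [
    "GridSearchSpec",
    "ClassifierModel",
    "build_training_set",
    "train_svm",
    "majority_vote",
    "classify_token",
    "classify_tokens",
]


@dataclass
class GridSearchSpec:
    """Hyperparameter grid for the C-SVC / RBF search.

    Defaults follow the usual coarse exponential grid: C = 2^-5..2^15 and
    gamma = 2^-15..2^3, both in steps of 2^2, with 5-fold CV.
    """

    C_grid: Sequence[float] = field(
        default_factory=lambda: [2.0**e for e in range(-5, 16, 2)]
    )
    gamma_grid: Sequence[float] = field(
        default_factory=lambda: [2.0**e for e in range(-15, 4, 2)]
    )
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not len(self.C_grid) or not len(self.gamma_grid):
            raise ValueError("grids must be non-empty")
        if min(self.C_grid) <= 0 or min(self.gamma_grid) <= 0:
            raise ValueError("C and gamma must be positive")

    @classmethod
    def small(cls, seed: int = 0) -> "GridSearchSpec":
        """A reduced grid for quick experiments and tests."""
        return cls(
            C_grid=[2.0**e for e in range(-1, 10, 2)],
            gamma_grid=[2.0**e for e in range(-7, 2, 2)],
            folds=5,
            seed=seed,
        )


@dataclass
class ClassifierModel:
    svm: SVC
    C: float
    gamma: float
    scaler: StandardScaler
    feature_set: FeatureSet
    classes: tuple[FricativeGroup, ...] = (
        FricativeGroup.NONSIB,
        FricativeGroup.ALV,
        FricativeGroup.PAL,
    )
    cv_accuracy: float = float("nan")


def _token_features(
    token: PhoneToken,
    feature_set: FeatureSet,
    bank: GammatoneBank | None,
    mode: FrameMode,
    seed: int,
    frame_ms: float,
) -> np.ndarray:
    frames = frame_token(token, frame_ms=frame_ms, mode=mode, seed=seed)
    return np.vstack(
        [compute_features(f, token.fs, feature_set, bank=bank).values for f in frames]
    )


def build_training_set(
    tokens: Sequence[PhoneToken],
    feature_set: FeatureSet,
    masker: Utterance,
    ssn_snr_db: float = TRAIN_SSN_SNR_DB,
    seed: int = 0,
    frame_ms: float = 8.0,
    bank: GammatoneBank | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two feature rows per token: one clean frame, one SSN-corrupted frame.

    Returns (features [2*len(tokens) x d], labels as group integers).
    """
    if not tokens:
        raise ValueError("no training tokens")
    if bank is None and feature_set in (FeatureSet.GT14, FeatureSet.GT24):
        bank = make_gammatone_bank(fs=tokens[0].fs)
    seeds = np.random.SeedSequence(seed).spawn(len(tokens))
    rows, labels = [], []
    for token, ss in zip(tokens, seeds):
        sub = ss.generate_state(3)
        rows.append(
            _token_features(
                token, feature_set, bank, FrameMode.RANDOM_ONE, int(sub[0]), frame_ms
            )[0]
        )
        noisy = mix_at_snr(
            Utterance(token.utterance_id, token.samples, token.fs),
            masker,
            ssn_snr_db,
            seed=int(sub[1]),
        )
        noisy_token = PhoneToken(
            token.utterance_id, token.group, noisy.samples, token.fs, token.phone
        )
        rows.append(
            _token_features(
                noisy_token, feature_set, bank, FrameMode.RANDOM_ONE, int(sub[2]), frame_ms
            )[0]
        )
        labels.extend([int(token.group)] * 2)
    return np.vstack(rows), np.asarray(labels, dtype=int)


def train_svm(
    features: np.ndarray,
    labels: np.ndarray,
    grid: GridSearchSpec | None = None,
    feature_set: FeatureSet = FeatureSet.GT14,
) -> ClassifierModel:
    """Grid-searched C-SVC with RBF kernel, one-against-one, refit on all rows."""
    grid = grid or GridSearchSpec()
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to train")
    if counts.min() < grid.folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; need >= {grid.folds} folds"
        )
    if not np.any(features.std(axis=0) > 0):
        raise ValueError("all feature dimensions are constant")

    scaler = StandardScaler().fit(features)
    Xs = scaler.transform(features)
    skf = StratifiedKFold(n_splits=grid.folds, shuffle=True, random_state=grid.seed)
    splits = list(skf.split(Xs, labels))

    best = (-np.inf, None, None)
    for C in sorted(grid.C_grid):
        for gamma in sorted(grid.gamma_grid):
            correct = 0
            for train_idx, val_idx in splits:
                clf = SVC(C=C, gamma=gamma, kernel="rbf")
                clf.fit(Xs[train_idx], labels[train_idx])
                correct += int(
                    np.sum(clf.predict(Xs[val_idx]) == labels[val_idx])
                )
            acc = correct / labels.size
            # strict improvement only: ties keep the earlier (smaller C,
            # then smaller gamma) grid point
            if acc > best[0]:
                best = (acc, C, gamma)
    cv_acc, C, gamma = best
    svm = SVC(C=C, gamma=gamma, kernel="rbf", decision_function_shape="ovo").fit(
        Xs, labels
    )
    return ClassifierModel(
        svm=svm,
        C=C,
        gamma=gamma,
        scaler=scaler,
        feature_set=feature_set,
        cv_accuracy=cv_acc,
    )


def _ovo_class_margins(svm: SVC, X: np.ndarray) -> np.ndarray:
    """Summed signed one-vs-one decision values per class, per row."""
    dec = svm.decision_function(X)
    if dec.ndim == 1:
        dec = dec[:, None]
    n_classes = len(svm.classes_)
    margins = np.zeros((X.shape[0], n_classes))
    col = 0
    for i in range(n_classes):
        for j in range(i + 1, n_classes):
            margins[:, i] += dec[:, col]
            margins[:, j] -= dec[:, col]
            col += 1
    return margins


def majority_vote(
    frame_pred: Sequence[int],
    class_margins: np.ndarray | None = None,
    n_classes: int = 3,
) -> int:
    """Modal frame label; ties -> largest summed margin, then lowest index.

    ``class_margins`` are per-class summed one-vs-one decision values over
    all frames; when omitted, ties fall straight to the lowest class index.
    The result is invariant to the order of ``frame_pred``.
    """
    counts = np.bincount(np.asarray(frame_pred, dtype=int), minlength=n_classes)
    tied = np.flatnonzero(counts == counts.max())
    if tied.size == 1 or class_margins is None:
        return int(tied[0])
    best = np.full(n_classes, -np.inf)
    best[tied] = np.asarray(class_margins)[tied]
    return int(np.argmax(best))


def classify_token(
    model: ClassifierModel,
    token: PhoneToken,
    reducer: ProjectionModel | None = None,
    frame_ms: float = 8.0,
    bank: GammatoneBank | None = None,
) -> tuple[FricativeGroup, list[FricativeGroup]]:
    """Label every 8-ms frame and majority-vote the token label."""
    if bank is None and model.feature_set in (FeatureSet.GT14, FeatureSet.GT24):
        bank = make_gammatone_bank(fs=token.fs)
    X = _token_features(token, model.feature_set, bank, FrameMode.ALL, 0, frame_ms)
    if reducer is not None:
        X = project(reducer, X)
    if X.shape[1] != model.scaler.mean_.size:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match the model "
            f"({model.scaler.mean_.size})"
        )
    Xs = model.scaler.transform(X)
    frame_pred = model.svm.predict(Xs)
    frame_labels = [FricativeGroup(int(p)) for p in frame_pred]

    margins = _ovo_class_margins(model.svm, Xs).sum(axis=0)
    full = np.full(len(model.classes), -np.inf)
    for pos, c in enumerate(model.svm.classes_):
        full[int(c)] = margins[pos]
    winner = majority_vote(frame_pred, full, n_classes=len(model.classes))
    return FricativeGroup(winner), frame_labels


def classify_tokens(
    model: ClassifierModel,
    tokens: Sequence[PhoneToken],
    reducer: ProjectionModel | None = None,
    frame_ms: float = 8.0,
    bank: GammatoneBank | None = None,
) -> list[FricativeGroup]:
    return [
        classify_token(model, t, reducer=reducer, frame_ms=frame_ms, bank=bank)[0]
        for t in tokens
    ]
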