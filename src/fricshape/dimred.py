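"""Linear and kernel PCA with eigenvalue-threshold dimension selection.

Both reductions are fit on training features only and applied frozen to
test features. The retained dimension m is the number of eigenvalues above
a threshold — by default a relative threshold of 1% of the eigenvalue sum.

Linear PCA eigendecomposes the 1/l-normalized covariance of the centered
data. Kernel PCA eigendecomposes the doubly-centered Gram matrix
G = K - 1K - K1 + 1K1 (1 the l x l matrix of entries 1/l); dual vectors are
normalized so that training projections have variance equal to the reported
eigenvalues, which makes the linear-kernel case coincide with linear PCA up
to per-dimension sign.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist

__all__ = ["ReductionKind", "KernelSpec", "ProjectionModel", "fit_pca", "fit_kpca", "project"]


class ReductionKind(enum.Enum):
    LDR = "ldr"  # linear (PCA)
    NLDR = "nldr"  # nonlinear (kernel PCA)


@dataclass
class KernelSpec:
    """Kernel for the nonlinear reduction; gamma=None means the median
    pairwise-distance heuristic is resolved at fit time."""

    name: str = "rbf"  # "rbf" or "linear"
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.name not in ("rbf", "linear"):
            raise ValueError(f"unsupported kernel {self.name!r}")


@dataclass
class ProjectionModel:
    kind: ReductionKind
    eigenvalues: np.ndarray  # descending, full spectrum
    m: int
    threshold: float
    # LDR fields
    train_mean: np.ndarray | None = None
    components: np.ndarray | None = None  # n x m, orthonormal columns
    # NLDR fields
    kernel: KernelSpec | None = None
    X_train: np.ndarray | None = None
    alphas: np.ndarray | None = None  # l x m dual coefficients
    K_train: np.ndarray | None = None  # uncentered training kernel matrix

    def save(self, path: str | Path) -> None:
        doc = {
            "schema": 1,
            "kind": self.kind.value,
            "eigenvalues": self.eigenvalues.tolist(),
            "m": self.m,
            "threshold": self.threshold,
        }
        if self.kind is ReductionKind.LDR:
            doc["train_mean"] = self.train_mean.tolist()
            doc["components"] = self.components.tolist()
        else:
            doc["kernel"] = {"name": self.kernel.name, "gamma": self.kernel.gamma}
            doc["X_train"] = self.X_train.tolist()
            doc["alphas"] = self.alphas.tolist()
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path: str | Path) -> "ProjectionModel":
        doc = json.loads(Path(path).read_text())
        kind = ReductionKind(doc["kind"])
        model = cls(
            kind=kind,
            eigenvalues=np.array(doc["eigenvalues"]),
            m=doc["m"],
            threshold=doc["threshold"],
        )
        if kind is ReductionKind.LDR:
            model.train_mean = np.array(doc["train_mean"])
            model.components = np.array(doc["components"])
        else:
            model.kernel = KernelSpec(**doc["kernel"])
            model.X_train = np.array(doc["X_train"])
            model.alphas = np.array(doc["alphas"])
            model.K_train = _kernel_matrix(model.X_train, model.X_train, model.kernel)
        return model


def _resolve_threshold(
    eigenvalues: np.ndarray, threshold: float, mode: str
) -> tuple[float, int]:
    if mode == "relative":
        cut = threshold * float(np.sum(np.clip(eigenvalues, 0.0, None)))
    elif mode == "absolute":
        cut = threshold
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    m = int(np.count_nonzero(eigenvalues > cut))
    return cut, max(m, 1)


def _sorted_eig(sym: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenpairs of a symmetric matrix, stably sorted descending."""
    w, v = np.linalg.eigh(sym)
    order = np.argsort(-w, kind="stable")
    return w[order], v[:, order]


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    flip = np.sign(vectors[np.argmax(np.abs(vectors), axis=0), np.arange(vectors.shape[1])])
    flip[flip == 0] = 1.0
    return vectors * flip


def fit_pca(
    X: np.ndarray, threshold: float = 0.01, threshold_mode: str = "relative"
) -> ProjectionModel:
    """Linear PCA of an l x n feature matrix (covariance normalized by 1/l)."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be an l x n matrix with l >= 2")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / X.shape[0]
    w, v = _sorted_eig(cov)
    if w[0] <= 0:
        raise ValueError("data has zero variance (all rows identical)")
    cut, m = _resolve_threshold(w, threshold, threshold_mode)
    return ProjectionModel(
        kind=ReductionKind.LDR,
        eigenvalues=w,
        m=m,
        threshold=cut,
        train_mean=mean,
        components=_fix_signs(v)[:, :m],
    )


def _kernel_matrix(A: np.ndarray, B: np.ndarray, kernel: KernelSpec) -> np.ndarray:
    if kernel.name == "linear":
        return A @ B.T
    sq = (
        np.sum(A * A, axis=1)[:, None]
        + np.sum(B * B, axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    return np.exp(-kernel.gamma * np.clip(sq, 0.0, None))


def _median_heuristic_gamma(X: np.ndarray) -> float:
    d = pdist(X)
    med = np.median(d[d > 0]) if np.any(d > 0) else 1.0
    return 1.0 / (2.0 * med**2)


def fit_kpca(
    X: np.ndarray,
    kernel: KernelSpec | None = None,
    threshold: float = 0.01,
    threshold_mode: str = "relative",
) -> ProjectionModel:
    """Kernel PCA via the centered Gram matrix of an l x n feature matrix."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be an l x n matrix with l >= 2")
    kernel = kernel or KernelSpec()
    if kernel.name == "rbf" and kernel.gamma is None:
        kernel = KernelSpec("rbf", _median_heuristic_gamma(X))
    l = X.shape[0]
    K = _kernel_matrix(X, X, kernel)
    ones = np.full((l, l), 1.0 / l)
    G = K - ones @ K - K @ ones + ones @ K @ ones
    mu, v = _sorted_eig(G)
    tol = 1e-8 * max(float(np.max(np.abs(mu))), 1.0)
    if float(np.min(mu)) < -tol:
        raise ValueError("kernel matrix is not positive semidefinite")
    # report eigenvalues on the covariance scale so the threshold rule is
    # directly comparable with linear PCA
    eigenvalues = mu / l
    cut, m = _resolve_threshold(eigenvalues, threshold, threshold_mode)
    v = _fix_signs(v)
    alphas = np.zeros((l, m))
    for i in range(m):
        if mu[i] > 0:
            alphas[:, i] = v[:, i] / np.sqrt(mu[i])
    return ProjectionModel(
        kind=ReductionKind.NLDR,
        eigenvalues=eigenvalues,
        m=m,
        threshold=cut,
        kernel=kernel,
        X_train=X.copy(),
        alphas=alphas,
        K_train=K,
    )


def project(model: ProjectionModel, x: np.ndarray) -> np.ndarray:
    """Map one vector or a stack of vectors into the reduced space."""
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if model.kind is ReductionKind.LDR:
        if X.shape[1] != model.train_mean.size:
            raise ValueError(
                f"dimension mismatch: got {X.shape[1]}, trained on "
                f"{model.train_mean.size}"
            )
        Y = (X - model.train_mean) @ model.components
    else:
        if X.shape[1] != model.X_train.shape[1]:
            raise ValueError(
                f"dimension mismatch: got {X.shape[1]}, trained on "
                f"{model.X_train.shape[1]}"
            )
        k = _kernel_matrix(X, model.X_train, model.kernel)
        # test-row centering consistent with the training Gram centering
        K = model.K_train
        k_c = (
            k
            - K.mean(axis=0)[None, :]
            - k.mean(axis=1, keepdims=True)
            + K.mean()
        )
        Y = k_c @ model.alphas
    return Y[0] if single else Y
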