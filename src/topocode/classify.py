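"""Four-class cell-cycle phase classification with a kernel SVM.

The classifier is one-vs-rest over the canonical phase order
(interphase, prophase, metaphase, anaphase) with a Gaussian RBF kernel
k(u, v) = exp(-||u - v||^2 / delta). A literal squared-distance kernel
||u - v||^2 / delta is available behind a flag for fidelity experiments;
it is monotone increasing in distance and not positive semidefinite, so
it is never the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .synthetic import PHASES

__all__ = ["SvmConfig", "ClassifierModel", "rbf_kernel", "kernel_matrix", "train_svm", "predict"]


@dataclass(frozen=True)
class SvmConfig:
    """Kernel width delta (squared feature-space units), soft-margin
    weight, and the kernel-form flag. delta and C_svm are not fixed by
    any canonical reference; the defaults are plain choices documented
    here and overridable in every entry point."""

    delta: float = 0.5
    C_svm: float = 100.0
    literal_kernel: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.C_svm <= 0:
            raise ValueError("delta and C_svm must be positive")


def rbf_kernel(u: np.ndarray, v: np.ndarray, delta: float, literal: bool = False) -> float:
    """k(u, v) = exp(-||u - v||^2 / delta), or the literal squared
    distance over delta when ``literal``."""
    u = np.asarray(u, dtype=np.float64).ravel()
    v = np.asarray(v, dtype=np.float64).ravel()
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    if delta <= 0:
        raise ValueError("delta must be positive")
    sq = float(np.sum((u - v) ** 2))
    return sq / delta if literal else float(np.exp(-sq / delta))


def kernel_matrix(
    X: np.ndarray, Y: np.ndarray, delta: float, literal: bool = False
) -> np.ndarray:
    """Pairwise kernel between columns of X (d x n) and Y (d x m)."""
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("feature dimensions differ")
    sq = (
        np.sum(X * X, axis=0)[:, None]
        + np.sum(Y * Y, axis=0)[None, :]
        - 2.0 * (X.T @ Y)
    )
    np.maximum(sq, 0.0, out=sq)
    return sq / delta if literal else np.exp(-sq / delta)


@dataclass
class ClassifierModel:
    """One binary SVC per phase (canonical order) on the shared kernel."""

    classes: tuple[str, ...]
    estimators: list[SVC]
    train_features: np.ndarray  # d x N, needed for the precomputed kernel
    config: SvmConfig


def train_svm(
    features: np.ndarray, labels: list[str] | tuple[str, ...], cfg: SvmConfig
) -> ClassifierModel:
    """Fit a one-vs-rest kernel SVM on columns of ``features``.

    Classes are taken in canonical phase order restricted to those
    present; fewer than two classes is an error.
    """
    X = np.asarray(features, dtype=np.float64)
    labels = list(labels)
    if X.ndim != 2 or X.shape[1] != len(labels):
        raise ValueError("need one label per feature column")
    present = tuple(p for p in PHASES if p in labels)
    extra = set(labels) - set(PHASES)
    if extra:
        raise ValueError(f"unknown phase labels: {sorted(extra)}")
    if len(present) < 2:
        raise ValueError("training requires at least two classes")
    K = kernel_matrix(X, X, cfg.delta, cfg.literal_kernel)
    y = np.array(labels)
    estimators = []
    for cls in present:
        est = SVC(C=cfg.C_svm, kernel="precomputed", random_state=cfg.seed)
        est.fit(K, (y == cls).astype(int))
        estimators.append(est)
    return ClassifierModel(present, estimators, X.copy(), cfg)


def decision_values(model: ClassifierModel, features: np.ndarray) -> np.ndarray:
    """n_classes x N matrix of one-vs-rest decision values."""
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("features must be a d x N matrix with N >= 1")
    if X.shape[0] != model.train_features.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[0]} does not match training "
            f"dimension {model.train_features.shape[0]}"
        )
    K = kernel_matrix(X, model.train_features, model.config.delta, model.config.literal_kernel)
    return np.vstack([est.decision_function(K) for est in model.estimators])


def predict(model: ClassifierModel, features: np.ndarray) -> list[str]:
    """One phase label per column; ties go to the highest decision value,
    then to the earliest class in canonical order."""
    D = decision_values(model, features)
    # np.argmax returns the first maximum, which is the canonical tie-break
    return [model.classes[i] for i in np.argmax(D, axis=0)]
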