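"""Extreme learning machine (ELM) and its kernelized closed form (KELM)
for two-class mounting / non-mounting classification.

An ELM is a single-hidden-layer feed-forward network whose hidden weights
``w`` and biases ``b`` are drawn at random and never trained; only the
output weights are fitted, by minimum-norm least squares::

    H[i, j] = g(x_i . w_j + b_j)        beta = H^+ T

where ``T`` is the N x 2 one-hot (+1/-1) target matrix. The kernel variant
never materializes the hidden layer: with Omega[i, j] = K(x_i, x_j) the
output coefficients solve the regularized symmetric system

    (I / C + Omega) A = T

in closed form, and a new point x is scored as ``[K(x, x_1) ... K(x, x_N)] A``.
The predicted class is the argmax of the two decision values; an exact tie
goes to the negative (non-mounting) class.

Training is deterministic for KELM; ELM randomness is fully fixed by its
seed. Features are z-scored per dimension from the training set by default
(perimeters, areas and distances live on very different scales, which an
RBF kernel would otherwise conflate); the standardization is stored in the
model and re-applied at prediction time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import linalg
from scipy.spatial.distance import cdist

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "KernelSpec",
    "KELMModel",
    "ELMModel",
    "label_matrix",
    "kernel_matrix",
    "kelm_train",
    "kelm_predict",
    "elm_train",
    "elm_predict",
    "save_kelm",
    "load_kelm",
]

POSITIVE = "positive"
NEGATIVE = "negative"
CLASSES = (POSITIVE, NEGATIVE)

FORMAT_VERSION = 1


@dataclass(frozen=True)
class KernelSpec:
    """A positive semi-definite kernel family with its parameters."""

    family: str = "rbf"
    gamma: float = 0.1  # rbf width: K(u, v) = exp(-gamma * ||u - v||^2)
    degree: int = 2  # polynomial only
    coef0: float = 1.0  # polynomial only

    def __post_init__(self) -> None:
        if self.family not in ("rbf", "linear", "polynomial"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family == "rbf" and not self.gamma > 0:
            raise ValueError(f"rbf gamma must be > 0, got {self.gamma}")
        if self.family == "polynomial" and self.degree < 1:
            raise ValueError(f"polynomial degree must be >= 1, got {self.degree}")


def label_matrix(labels: Sequence[str]) -> np.ndarray:
    """N x 2 one-hot target matrix: row [+1, -1] for positive, [-1, +1] for negative."""
    T = np.empty((len(labels), 2))
    for i, lab in enumerate(labels):
        if lab == POSITIVE:
            T[i] = (1.0, -1.0)
        elif lab == NEGATIVE:
            T[i] = (-1.0, 1.0)
        else:
            raise ValueError(f"unknown class label {lab!r} (expected one of {CLASSES})")
    return T


def _check_features(X: np.ndarray, name: str = "X") -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"{name} must be 2-D (samples x features), got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError(f"{name} contains non-finite values")
    return X


def kernel_matrix(X: np.ndarray, Y: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Gram matrix K with K[i, j] = K(X_i, Y_j)."""
    X = _check_features(X, "X")
    Y = _check_features(Y, "Y")
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"feature dimensions differ: {X.shape[1]} vs {Y.shape[1]}")
    if spec.family == "rbf":
        return np.exp(-spec.gamma * cdist(X, Y, "sqeuclidean"))
    if spec.family == "linear":
        return X @ Y.T
    return (X @ Y.T + spec.coef0) ** spec.degree


# ---------------------------------------------------------------------------
# KELM


@dataclass
class KELMModel:
    """Closed-form kernel ELM: stored training inputs plus coefficients A."""

    X_train: np.ndarray  # standardized training features, N x n
    kernel: KernelSpec
    C_reg: float
    A: np.ndarray  # N x 2 output coefficients
    mean: np.ndarray  # per-dimension standardization
    std: np.ndarray
    classes: tuple[str, str] = CLASSES

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std


def _fit_standardizer(X: np.ndarray, enabled: bool) -> tuple[np.ndarray, np.ndarray]:
    n = X.shape[1]
    if not enabled:
        return np.zeros(n), np.ones(n)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0.0] = 1.0  # constant feature (e.g. padding slots): leave centred
    return mean, std


def kelm_train(
    X: np.ndarray,
    labels: Sequence[str],
    spec: KernelSpec = KernelSpec(),
    C_reg: float = 1.0,
    standardize: bool = True,
) -> KELMModel:
    """Fit the kernel ELM in closed form.

    Solves the symmetric positive-definite system ``(I / C + Omega) A = T``
    (never forming an explicit inverse). Deterministic: no randomness enters
    KELM training.
    """
    X = _check_features(X)
    if len(labels) != X.shape[0]:
        raise ValueError(f"{X.shape[0]} samples but {len(labels)} labels")
    if not C_reg > 0:
        raise ValueError(f"regularization C_reg must be > 0, got {C_reg}")
    T = label_matrix(labels)
    if len(set(labels)) == 1:
        warnings.warn("training set contains a single class; predictions will be constant")
    mean, std = _fit_standardizer(X, standardize)
    Xs = (X - mean) / std
    omega = kernel_matrix(Xs, Xs, spec)
    system = omega + np.eye(len(Xs)) / C_reg
    A = linalg.solve(system, T, assume_a="pos")
    return KELMModel(X_train=Xs, kernel=spec, C_reg=float(C_reg), A=A, mean=mean, std=std)


def _decide(decision: np.ndarray, classes: tuple[str, str]) -> list[str]:
    # argmax over the two outputs; exact tie -> negative class
    labels = []
    for pos_score, neg_score in decision:
        labels.append(classes[0] if pos_score > neg_score else classes[1])
    return labels


def kelm_predict(model: KELMModel, X_new: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Decision values (M x 2) and predicted class labels for new points."""
    X_new = _check_features(X_new, "X_new")
    if X_new.shape[1] != model.X_train.shape[1]:
        raise ValueError(
            f"feature dimension {X_new.shape[1]} does not match "
            f"training dimension {model.X_train.shape[1]}"
        )
    K = kernel_matrix(model.standardize(X_new), model.X_train, model.kernel)
    decision = K @ model.A
    return decision, _decide(decision, model.classes)


# ---------------------------------------------------------------------------
# ELM (explicit random hidden layer)

_ACTIVATIONS = {
    "sigmoid": lambda z: 1.0 / (1.0 + np.exp(-z)),
    "tanh": np.tanh,
    "identity": lambda z: z,
    "sin": np.sin,
}


@dataclass
class ELMModel:
    W: np.ndarray  # n x m input weights
    b: np.ndarray  # m hidden biases
    activation: str
    beta: np.ndarray  # m x 2 output weights
    mean: np.ndarray
    std: np.ndarray
    seed: int | None = None
    classes: tuple[str, str] = CLASSES

    def hidden(self, X: np.ndarray) -> np.ndarray:
        g = _ACTIVATIONS[self.activation]
        return g((X - self.mean) / self.std @ self.W + self.b)


def elm_train(
    X: np.ndarray,
    labels: Sequence[str],
    m: int,
    activation: str = "sigmoid",
    seed: int | None = 0,
    standardize: bool = True,
    W: np.ndarray | None = None,
    b: np.ndarray | None = None,
) -> ELMModel:
    """Fit an ELM: random hidden layer, minimum-norm least-squares output.

    Hidden weights and biases are uniform on [-1, 1], fully determined by
    ``seed``; pass explicit ``W``/``b`` to pin the hidden layer (used e.g.
    to recover plain linear least squares with the identity activation).
    """
    X = _check_features(X)
    if m < 1:
        raise ValueError(f"hidden node count m must be >= 1, got {m}")
    if activation not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r} (known: {sorted(_ACTIVATIONS)})")
    if len(labels) != X.shape[0]:
        raise ValueError(f"{X.shape[0]} samples but {len(labels)} labels")
    T = label_matrix(labels)
    mean, std = _fit_standardizer(X, standardize)
    Xs = (X - mean) / std
    rng = np.random.default_rng(seed)
    if W is None:
        W = rng.uniform(-1.0, 1.0, size=(X.shape[1], m))
    if b is None:
        b = rng.uniform(-1.0, 1.0, size=m)
    H = _ACTIVATIONS[activation](Xs @ W + b)
    beta, *_ = np.linalg.lstsq(H, T, rcond=None)  # beta = H^+ T, minimum norm
    return ELMModel(W=W, b=b, activation=activation, beta=beta, mean=mean, std=std, seed=seed)


def elm_predict(model: ELMModel, X_new: np.ndarray) -> tuple[np.ndarray, list[str]]:
    X_new = _check_features(X_new, "X_new")
    if X_new.shape[1] != model.W.shape[0]:
        raise ValueError(
            f"feature dimension {X_new.shape[1]} does not match "
            f"training dimension {model.W.shape[0]}"
        )
    decision = model.hidden(X_new) @ model.beta
    return decision, _decide(decision, model.classes)


# ---------------------------------------------------------------------------
# serialization


def save_kelm(model: KELMModel, path: str | Path) -> None:
    """Serialize a KELM model to one JSON document (with a format version)."""
    doc = {
        "format_version": FORMAT_VERSION,
        "model_type": "kelm",
        "kernel": {
            "family": model.kernel.family,
            "gamma": model.kernel.gamma,
            "degree": model.kernel.degree,
            "coef0": model.kernel.coef0,
        },
        "C_reg": model.C_reg,
        "classes": list(model.classes),
        "mean": model.mean.tolist(),
        "std": model.std.tolist(),
        "X_train": model.X_train.tolist(),
        "A": model.A.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def load_kelm(path: str | Path) -> KELMModel:
    doc = json.loads(Path(path).read_text())
    version = doc.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version!r}")
    if doc.get("model_type") != "kelm":
        raise ValueError(f"not a KELM model file: type {doc.get('model_type')!r}")
    k = doc["kernel"]
    return KELMModel(
        X_train=np.asarray(doc["X_train"], dtype=float),
        kernel=KernelSpec(family=k["family"], gamma=k["gamma"], degree=k["degree"], coef0=k["coef0"]),
        C_reg=float(doc["C_reg"]),
        A=np.asarray(doc["A"], dtype=float),
        mean=np.asarray(doc["mean"], dtype=float),
        std=np.asarray(doc["std"], dtype=float),
        classes=tuple(doc["classes"]),
    )
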