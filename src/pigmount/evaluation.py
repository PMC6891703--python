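"""Evaluation: confusion accounting, the four classification metrics
(specificity, sensitivity, accuracy, Matthews correlation coefficient),
mean pixel accuracy for segmentation, K-fold cross-validation with grid
search, and the negative-sample balancing step.

Zero-division policy: any metric term whose denominator is zero evaluates
to 0 with a logged warning (for MCC the common convention — any zero factor
under the root makes MCC 0). This keeps batch evaluation total on
degenerate confusion matrices.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .kelm import NEGATIVE, POSITIVE, KELMModel, KernelSpec, kelm_predict, kelm_train

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "SegmentationEval",
    "CVPlan",
    "GridSearchResult",
    "confusion",
    "classification_metrics",
    "mean_pixel_accuracy",
    "make_folds",
    "grid_search_cv",
    "balance_negatives",
    "metrics_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class SegmentationEval:
    """Per-class pixel tallies P[i, j]: true class i predicted as class j.

    Class 0 is background; classes 1..k are the foreground categories
    (here k = 1, the single class "pig").
    """

    P: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=np.int64)
        if self.P.ndim != 2 or self.P.shape[0] != self.P.shape[1]:
            raise ValueError(f"pixel tally must be square, got shape {self.P.shape}")
        if (self.P < 0).any():
            raise ValueError("pixel tallies must be non-negative")

    @property
    def k(self) -> int:
        """Number of classes excluding background."""
        return self.P.shape[0] - 1

    @classmethod
    def from_masks(cls, truth: np.ndarray, predicted: np.ndarray) -> "SegmentationEval":
        """Tally binary background/pig masks into the 2 x 2 pixel table."""
        truth = np.asarray(truth).astype(bool)
        predicted = np.asarray(predicted).astype(bool)
        if truth.shape != predicted.shape:
            raise ValueError(f"shape mismatch: {truth.shape} vs {predicted.shape}")
        P = np.zeros((2, 2), dtype=np.int64)
        for i in (0, 1):
            for j in (0, 1):
                P[i, j] = int(np.sum((truth == bool(i)) & (predicted == bool(j))))
        return cls(P)


def confusion(predicted: Sequence[str], truth: Sequence[str]) -> ConfusionMatrix:
    """Count TP/TN/FP/FN from per-sample class labels."""
    if len(predicted) != len(truth):
        raise ValueError(f"length mismatch: {len(predicted)} predictions, {len(truth)} truths")
    counts = {"TP": 0, "TN": 0, "FP": 0, "FN": 0}
    for p, t in zip(predicted, truth):
        for lab in (p, t):
            if lab not in (POSITIVE, NEGATIVE):
                raise ValueError(f"unknown label {lab!r}")
        if t == POSITIVE:
            counts["TP" if p == POSITIVE else "FN"] += 1
        else:
            counts["FP" if p == POSITIVE else "TN"] += 1
    return ConfusionMatrix(**counts)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("zero denominator in %s; reporting 0 by policy", what)
        return 0.0
    return num / den


def classification_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Specificity, sensitivity, accuracy and MCC from a confusion matrix."""
    tp, tn, fp, fn = float(cm.TP), float(cm.TN), float(cm.FP), float(cm.FN)
    sp = _safe_div(tn, tn + fp, "specificity")
    sn = _safe_div(tp, tp + fn, "sensitivity")
    acc = _safe_div(tp + tn, tp + tn + fp + fn, "accuracy")
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    mcc = _safe_div(tp * tn - fp * fn, math.sqrt(denom), "MCC") if denom > 0 else _safe_div(0, 0, "MCC")
    return {"SP": sp, "SN": sn, "ACC": acc, "MCC": mcc}


def mean_pixel_accuracy(ev: SegmentationEval) -> float:
    """Average over the k+1 classes (background included) of per-class pixel recall."""
    recalls = []
    for i in range(ev.k + 1):
        row = ev.P[i].sum()
        recalls.append(_safe_div(float(ev.P[i, i]), float(row), f"MPA class {i}"))
    return float(np.mean(recalls))


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVPlan:
    """A seeded K-fold partition of N sample indices."""

    assignments: np.ndarray  # fold id per sample, length N
    K: int
    seed: int

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)

    @property
    def N(self) -> int:
        return len(self.assignments)

    def fold_indices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == k)

    def train_indices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != k)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"K": self.K, "seed": self.seed, "assignments": self.assignments.tolist()})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CVPlan":
        doc = json.loads(Path(path).read_text())
        return cls(assignments=np.asarray(doc["assignments"]), K=doc["K"], seed=doc["seed"])


def make_folds(
    N: int, K: int = 5, seed: int = 0, labels: Sequence[str] | None = None, stratify: bool = False
) -> CVPlan:
    """Randomly partition N samples into K folds with sizes differing by <= 1.

    ``stratify=True`` balances class proportions per fold (requires
    ``labels``); the default is the plain random split.
    """
    if N < K:
        raise ValueError(f"cannot split N={N} samples into K={K} folds")
    rng = np.random.default_rng(seed)
    assignments = np.empty(N, dtype=int)
    if stratify:
        if labels is None:
            raise ValueError("stratified folds need labels")
        order = []
        for cls_name in sorted(set(labels)):
            idx = [i for i, lab in enumerate(labels) if lab == cls_name]
            order.extend(rng.permutation(idx).tolist())
        for pos, i in enumerate(order):
            assignments[i] = pos % K
    else:
        perm = rng.permutation(N)
        for pos, i in enumerate(perm):
            assignments[i] = pos % K
    return CVPlan(assignments=assignments, K=K, seed=seed)


@dataclass
class GridSearchResult:
    best_gamma: float
    best_C: float
    kernel_family: str
    table: pd.DataFrame  # columns gamma, C, mean_score, n_folds_ok
    models: list[KELMModel] = field(default_factory=list)  # one per outer fold, best params

    @property
    def best_spec(self) -> KernelSpec:
        return KernelSpec(family=self.kernel_family, gamma=self.best_gamma)


def grid_search_cv(
    X: np.ndarray,
    labels: Sequence[str],
    gammas: Sequence[float],
    Cs: Sequence[float],
    plan: CVPlan,
    kernel_family: str = "rbf",
    score: str = "ACC",
) -> GridSearchResult:
    """K-fold cross-validated grid search over (gamma, C) for the KELM.

    Every grid cell gets a mean validation score over the folds; the best
    cell (ties broken toward smaller C, then smaller gamma) is refit once
    per outer fold, yielding K models whose test-set metrics are averaged
    downstream. A cell that fails to train is recorded and skipped.
    """
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    if len(gammas) == 0 or len(Cs) == 0:
        raise ValueError("empty hyperparameter grid")
    if plan.N != len(labels):
        raise ValueError(f"CV plan covers {plan.N} samples but {len(labels)} labels given")
    if score not in ("ACC", "MCC"):
        raise ValueError(f"model-selection score must be 'ACC' or 'MCC', got {score!r}")

    rows = []
    for gamma in gammas:
        for C in Cs:
            spec = KernelSpec(family=kernel_family, gamma=gamma)
            fold_scores = []
            for k in range(plan.K):
                tr, va = plan.train_indices(k), plan.fold_indices(k)
                try:
                    model = kelm_train(X[tr], [labels[i] for i in tr], spec=spec, C_reg=C)
                    _, pred = kelm_predict(model, X[va])
                except (ValueError, np.linalg.LinAlgError) as exc:
                    logger.warning("grid cell (gamma=%g, C=%g) fold %d failed: %s", gamma, C, k, exc)
                    continue
                cm = confusion(pred, [labels[i] for i in va])
                fold_scores.append(classification_metrics(cm)[score])
            rows.append(
                {
                    "gamma": gamma,
                    "C": C,
                    "mean_score": float(np.mean(fold_scores)) if fold_scores else float("nan"),
                    "n_folds_ok": len(fold_scores),
                }
            )
    table = pd.DataFrame(rows)
    ok = table[table.n_folds_ok > 0]
    if ok.empty:
        raise RuntimeError("every grid cell failed to train")
    # best mean score; ties -> smaller C, then smaller gamma
    best = ok.sort_values(["mean_score", "C", "gamma"], ascending=[False, True, True]).iloc[0]
    best_spec = KernelSpec(family=kernel_family, gamma=float(best.gamma))
    models = [
        kelm_train(
            X[plan.train_indices(k)],
            [labels[i] for i in plan.train_indices(k)],
            spec=best_spec,
            C_reg=float(best.C),
        )
        for k in range(plan.K)
    ]
    return GridSearchResult(
        best_gamma=float(best.gamma),
        best_C=float(best.C),
        kernel_family=kernel_family,
        table=table,
        models=models,
    )


def balance_negatives(
    table: pd.DataFrame, removal_count: int, seed: int = 0, label_col: str = "label"
) -> pd.DataFrame:
    """Remove exactly ``removal_count`` negative rows uniformly at random.

    Positives are untouched; row order of the survivors is preserved. This
    is the class-balancing step applied to a training feature table before
    classifier fitting.
    """
    if removal_count < 0:
        raise ValueError("removal_count must be >= 0")
    neg_idx = table.index[table[label_col] == NEGATIVE]
    if removal_count > len(neg_idx):
        raise ValueError(
            f"cannot remove {removal_count} negatives: only {len(neg_idx)} present"
        )
    rng = np.random.default_rng(seed)
    drop = rng.choice(neg_idx, size=removal_count, replace=False)
    return table.drop(index=drop)


def metrics_report(
    per_model: Sequence[dict[str, float]], as_json: str | Path | None = None
) -> pd.DataFrame:
    """Stack per-model metric dicts and append the mean row.

    The mean row mirrors the reporting convention for K outer-fold models
    evaluated on a common held-out test partition.
    """
    df = pd.DataFrame(per_model)
    df.index = [f"model_{i}" for i in range(len(df))]
    df.loc["mean"] = df.mean()
    if as_json is not None:
        Path(as_json).write_text(df.to_json(orient="index", indent=1))
    return df
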