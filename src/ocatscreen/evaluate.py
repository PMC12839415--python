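"""Classifier training and bootstrapped test-set evaluation.

Two screening models are supported: logistic regression (L2 penalty, L-BFGS,
default regularization, no class weights) scored at fixed decision
thresholds of 0.45 and 0.50 on the PMCI probability, and K-nearest
neighbours (Euclidean distance, uniform weights) with k chosen from 3..10 by
cross-validated grid search on the training data only.

Metrics (recall, precision, specificity, F1, accuracy, AUPRC) are reported
as bootstrap means with 95% percentile confidence intervals over resamples
of the held-out test set; the fitted model itself is not refitted per
replicate.  AUPRC uses the average-precision formulation (step-wise sum of
precision times recall increments), which avoids optimistic interpolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, f1_score, precision_recall_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

POSITIVE = "PMCI"
METRIC_NAMES = ("recall", "precision", "specificity", "f1", "accuracy", "auprc")
DEFAULT_THRESHOLDS = (0.45, 0.50)


class ConvergenceError(RuntimeError):
    pass


def _as_binary(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype == object or y.dtype.kind in "US":
        return (y == POSITIVE).astype(int)
    return y.astype(int)


def train_lr(
    train_X: pd.DataFrame | np.ndarray,
    train_y,
    C: float = 1.0,
    max_iter: int = 1000,
) -> LogisticRegression:
    """Fit an L2-penalized logistic regression (L-BFGS, no class weights)."""
    y = _as_binary(train_y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in training data")
    # default LogisticRegression is the L2-penalized L-BFGS formulation
    model = LogisticRegression(C=C, solver="lbfgs", max_iter=max_iter)
    model.fit(np.asarray(train_X, dtype=float), y)
    if model.n_iter_[0] >= max_iter:
        raise ConvergenceError(f"L-BFGS did not converge within {max_iter} iterations")
    return model


def predict_threshold(model, X, dt: float = 0.5) -> np.ndarray:
    """Positive (PMCI, 1) iff the predicted positive probability is >= dt."""
    if not (0 < dt < 1):
        raise ValueError("decision threshold must be in (0, 1)")
    proba = model.predict_proba(np.asarray(X, dtype=float))[:, 1]
    return (proba >= dt).astype(int)


def train_knn(
    train_X: pd.DataFrame | np.ndarray,
    train_y,
    k_grid=tuple(range(3, 11)),
    cv_folds: int = 5,
    seed: int = 0,
    criterion: str = "f1",
) -> tuple[KNeighborsClassifier, int]:
    """Grid-search k over ``k_grid`` by stratified cross-validation on the
    training data (mean F1 by default, accuracy optionally), then fit the
    winning k.  Ties break toward the smaller k."""
    k_grid = list(k_grid)
    if not k_grid:
        raise ValueError("k grid must not be empty")
    X = np.asarray(train_X, dtype=float)
    y = _as_binary(train_y)
    if len(X) < max(k_grid) + 1:
        raise ValueError("not enough training rows for the largest k")
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    best_k, best_score = None, -np.inf
    for k in k_grid:
        scores = []
        for tr, te in skf.split(X, y):
            knn = KNeighborsClassifier(n_neighbors=k, metric="euclidean", weights="uniform")
            knn.fit(X[tr], y[tr])
            pred = knn.predict(X[te])
            if criterion == "f1":
                scores.append(f1_score(y[te], pred, zero_division=0))
            elif criterion == "accuracy":
                scores.append(float(np.mean(pred == y[te])))
            else:
                raise ValueError(f"unknown criterion {criterion!r}")
        mean_score = float(np.mean(scores))
        if mean_score > best_score:
            best_k, best_score = k, mean_score
    model = KNeighborsClassifier(n_neighbors=best_k, metric="euclidean", weights="uniform")
    model.fit(X, y)
    return model, best_k


def confusion_metrics(y_true, y_pred) -> dict[str, float]:
    """Recall, precision, specificity, F1 and accuracy from binary labels.

    Zero-denominator metrics are reported as 0.0 and flagged under
    ``degenerate`` rather than returned as NaN.
    """
    yt = _as_binary(y_true)
    yp = _as_binary(y_pred)
    if len(yt) != len(yp):
        raise ValueError("y_true and y_pred must have the same length")
    tp = int(np.sum((yt == 1) & (yp == 1)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    degenerate = []

    def ratio(num, den, name):
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    recall = ratio(tp, tp + fn, "recall")
    precision = ratio(tp, tp + fp, "precision")
    specificity = ratio(tn, tn + fp, "specificity")
    f1 = ratio(2 * precision * recall, precision + recall, "f1") if (precision + recall) > 0 else 0.0
    if (precision + recall) == 0:
        degenerate.append("f1")
    accuracy = (tp + tn) / len(yt)
    out = {"recall": recall, "precision": precision, "specificity": specificity,
           "f1": f1, "accuracy": accuracy}
    out["degenerate"] = degenerate
    return out


def auprc(y_true, scores) -> float:
    """Area under the precision-recall curve (average precision)."""
    yt = _as_binary(y_true)
    if len(np.unique(yt)) < 2:
        raise ValueError("AUPRC undefined for single-class y_true")
    return float(average_precision_score(yt, np.asarray(scores, dtype=float)))


def pr_curve(y_true, scores) -> pd.DataFrame:
    """Precision-recall points at every distinct score threshold."""
    yt = _as_binary(y_true)
    precision, recall, thresholds = precision_recall_curve(yt, np.asarray(scores, dtype=float))
    return pd.DataFrame({
        "recall": recall[:-1][::-1],
        "precision": precision[:-1][::-1],
        "threshold": thresholds[::-1],
    })


@dataclass
class BootstrapSummary:
    mean: float
    lower: float
    upper: float
    point: float


@dataclass
class ModelReport:
    """Bootstrapped metric summary for one fitted model on the test set."""

    model: str
    config: dict = field(default_factory=dict)
    metrics: dict[str, BootstrapSummary] = field(default_factory=dict)
    pr_points: pd.DataFrame | None = None
    n_redrawn: int = 0

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "config": self.config,
            "n_redrawn_replicates": self.n_redrawn,
            "metrics": {
                name: {"mean": s.mean, "ci_lower": s.lower, "ci_upper": s.upper, "point": s.point}
                for name, s in self.metrics.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def format_cell(self, metric: str) -> str:
        s = self.metrics[metric]
        return f"{s.mean:.2f} [{s.lower:.2f}–{s.upper:.2f}]"


def bootstrap_metrics(
    y_true,
    scores,
    y_pred,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[dict[str, BootstrapSummary], int]:
    """Bootstrap the test set (same size, with replacement) B times and
    summarize each metric with its mean and percentile confidence interval.

    Replicates without a positive case are redrawn (their count is
    returned).  The same replicates are shared across all metrics.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    yt = _as_binary(y_true)
    scores = np.asarray(scores, dtype=float)
    yp = _as_binary(y_pred)
    n = len(yt)
    rng = np.random.default_rng(seed)
    rows = {name: [] for name in METRIC_NAMES}
    n_redrawn = 0
    for _ in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            if yt[idx].sum() > 0:
                break
            n_redrawn += 1
        cm = confusion_metrics(yt[idx], yp[idx])
        for name in ("recall", "precision", "specificity", "f1", "accuracy"):
            rows[name].append(cm[name])
        if len(np.unique(yt[idx])) == 2:
            rows["auprc"].append(auprc(yt[idx], scores[idx]))
        else:  # all-positive resample: every ranking is perfect
            rows["auprc"].append(1.0)
    alpha = (1 - level) / 2 * 100
    cm_point = confusion_metrics(yt, yp)
    points = {**{k: cm_point[k] for k in METRIC_NAMES if k != "auprc"},
              "auprc": auprc(yt, scores)}
    out = {}
    for name in METRIC_NAMES:
        vals = np.asarray(rows[name])
        out[name] = BootstrapSummary(
            mean=float(vals.mean()),
            lower=float(np.percentile(vals, alpha)),
            upper=float(np.percentile(vals, 100 - alpha)),
            point=float(points[name]),
        )
    return out, n_redrawn


def evaluate_model(
    model,
    test_X,
    test_y,
    model_name: str,
    dt: float | None = None,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    config: dict | None = None,
) -> ModelReport:
    """Score a fitted probability model on the held-out test set."""
    X = np.asarray(test_X, dtype=float)
    scores = model.predict_proba(X)[:, 1]
    preds = predict_threshold(model, X, dt) if dt is not None else model.predict(X)
    metrics, n_redrawn = bootstrap_metrics(test_y, scores, preds, B=B, level=level, seed=seed)
    return ModelReport(
        model=model_name,
        config=dict(config or {}, dt=dt),
        metrics=metrics,
        pr_points=pr_curve(test_y, scores),
        n_redrawn=n_redrawn,
    )
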