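"""Metrics, cross-validated reporting, paired tests and calibration.

Binary metrics treat the high-grade class (label 1) as positive; multiclass
metrics are macro-averaged (unweighted mean over classes).  Cross-validated
reports aggregate per-fold values as mean ± sd with a normal-approximation
95% confidence interval.  Q-values are mapped to class probabilities by a
softmax (temperature 1) — a convention for calibration utilities, since
Q-values are not trained as probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import binomtest, chi2
from sklearn.metrics import (
    accuracy_score,
    auc,
    confusion_matrix,
    precision_recall_curve,
    precision_recall_fscore_support,
    roc_curve,
)

from .table import SampleTable, kfold_splits

__all__ = [
    "MetricsReport",
    "classification_metrics",
    "crossval_report",
    "CrossValReport",
    "mcnemar_paired",
    "brier_score",
    "roc_pr_points",
    "softmax_probabilities",
]


@dataclass
class MetricsReport:
    """Precision/recall/F1/accuracy plus the confusion matrix."""

    precision: float
    recall: float
    f1: float
    accuracy: float
    confusion: np.ndarray
    averaging: str = "binary"

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "averaging": self.averaging,
            "confusion": self.confusion.tolist(),
        }


def classification_metrics(
    y_true: Sequence[int], y_pred: Sequence[int], averaging: str = "binary"
) -> MetricsReport:
    """Standard classification metrics.

    ``averaging='binary'`` scores the positive class (1, high-grade);
    ``'macro'`` takes the unweighted mean over classes (the multiclass
    survival convention).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if averaging not in ("binary", "macro"):
        raise ValueError("averaging must be 'binary' or 'macro'")
    p, r, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, average=averaging, zero_division=0
    )
    labels = np.unique(np.concatenate([y_true, y_pred]))
    return MetricsReport(
        precision=float(p),
        recall=float(r),
        f1=float(f1),
        accuracy=float(accuracy_score(y_true, y_pred)),
        confusion=confusion_matrix(y_true, y_pred, labels=labels),
        averaging=averaging,
    )


@dataclass
class CrossValReport:
    """Fold-level metric values with mean ± sd and normal 95% CI."""

    folds: list[MetricsReport]
    averaging: str

    def _vals(self, attr: str) -> np.ndarray:
        return np.array([getattr(f, attr) for f in self.folds])

    def summary(self) -> dict:
        out = {}
        for attr in ("precision", "recall", "f1", "accuracy"):
            v = self._vals(attr)
            mean, sd = float(v.mean()), float(v.std(ddof=0))
            half = 1.96 * sd / np.sqrt(len(v))
            out[attr] = {
                "mean": mean,
                "sd": sd,
                "ci95": (mean - half, mean + half),
                "per_fold": v.tolist(),
            }
        return out


def crossval_report(
    table: SampleTable,
    fit_predict: Callable[[SampleTable, SampleTable], np.ndarray],
    k: int = 5,
    seed: int = 0,
    averaging: str = "binary",
) -> CrossValReport:
    """Group-atomic stratified k-fold evaluation of a fit-and-predict routine.

    ``fit_predict(train_table, val_table)`` must fit everything — feature
    selection included — on the training fold only and return predicted
    labels for the validation fold; this is the leakage isolation contract.
    Folds whose validation side collapses to a single class are skipped with
    a warning.
    """
    reports: list[MetricsReport] = []
    for tr_idx, va_idx in kfold_splits(table, k=k, seed=seed):
        tr, va = table.subset_rows(tr_idx), table.subset_rows(va_idx)
        if len(np.unique(va.labels)) < 2:
            warnings.warn("validation fold has a single class; skipped", stacklevel=2)
            continue
        preds = fit_predict(tr, va)
        reports.append(classification_metrics(va.labels, preds, averaging=averaging))
    return CrossValReport(folds=reports, averaging=averaging)


def mcnemar_paired(
    y_true: Sequence[int], pred_a: Sequence[int], pred_b: Sequence[int]
) -> tuple[float, float]:
    """McNemar's paired test on two classifiers' discordant predictions.

    The statistic is the continuity-corrected (|b−c|−1)²/(b+c) on the
    discordant counts (b: A right & B wrong, c: A wrong & B right).  The
    p-value is the exact two-sided binomial tail when b+c < 25, else the
    χ²(1) tail of the corrected statistic.  Identical prediction vectors
    give (0.0, 1.0).
    """
    y = np.asarray(y_true)
    a_ok = np.asarray(pred_a) == y
    b_ok = np.asarray(pred_b) == y
    b_count = int(np.sum(a_ok & ~b_ok))
    c_count = int(np.sum(~a_ok & b_ok))
    n_disc = b_count + c_count
    if n_disc == 0:
        return 0.0, 1.0
    stat = (abs(b_count - c_count) - 1) ** 2 / n_disc
    if n_disc < 25:
        p = binomtest(min(b_count, c_count), n_disc, 0.5, alternative="two-sided").pvalue
    else:
        p = float(chi2.sf(stat, df=1))
    return float(stat), float(p)


def brier_score(probabilities: np.ndarray, y_true: Sequence[int]) -> float:
    """Mean squared distance between predicted probabilities and the truth.

    Binary input may be a 1-D vector of positive-class probabilities (the
    classical binary Brier score); otherwise rows are per-class probability
    vectors scored against one-hot truth.
    """
    y = np.asarray(y_true, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if p.ndim == 1:
        return float(np.mean((p - y) ** 2))
    onehot = np.zeros_like(p)
    onehot[np.arange(len(y)), y] = 1.0
    return float(np.mean(np.sum((p - onehot) ** 2, axis=1)))


def softmax_probabilities(q_values: np.ndarray) -> np.ndarray:
    """Temperature-1 softmax over Q-values, rowwise; rows sum to one."""
    q = np.atleast_2d(np.asarray(q_values, dtype=float))
    z = q - q.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class CurvePoints:
    """ROC and precision-recall sweeps with trapezoidal areas."""

    fpr: np.ndarray
    tpr: np.ndarray
    roc_auc: float
    precision: np.ndarray
    recall: np.ndarray
    pr_auc: float


def roc_pr_points(scores: Sequence[float], labels: Sequence[int]) -> CurvePoints:
    """Threshold sweep of positive-class scores; trapezoidal areas."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    fpr, tpr, _ = roc_curve(y, s)
    prec, rec, _ = precision_recall_curve(y, s)
    return CurvePoints(
        fpr=fpr,
        tpr=tpr,
        roc_auc=float(auc(fpr, tpr)),
        precision=prec,
        recall=rec,
        pr_auc=float(auc(rec, prec)),
    )
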