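"""Evaluation metrics for the classification and regression tasks.

Confusion-matrix metrics (accuracy, recall, precision, F1) operate on
explicit TP/TN/FP/FN counts; ROC AUC on scores.  The regression metrics
come in two flavours where the source formulas are unusual:

* ``rmse_as_printed`` averages ``sqrt((y − y′)²)`` term by term, which is
  algebraically the mean absolute error; ``rmse_standard`` is the usual
  ``sqrt(mean((y − y′)²))``.
* ``varscore_as_printed`` is ``(1/n) (1 − V(y−y′)/V(y))`` with the
  leading ``1/n`` applied literally; ``explained_variance`` omits it and
  equals 1 for perfect predictions.

Variances use the population convention (divide by ``n``).  Run reports
use the standard variants and label which was used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionCounts",
    "confusion_from_labels",
    "accuracy",
    "recall",
    "precision",
    "f1_score",
    "auc",
    "rmse_as_printed",
    "rmse_standard",
    "mae",
    "pcc",
    "varscore_as_printed",
    "explained_variance",
    "classification_report",
    "regression_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    n_tp: int
    n_tn: int
    n_fp: int
    n_fn: int

    def __post_init__(self) -> None:
        if min(self.n_tp, self.n_tn, self.n_fp, self.n_fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_tp + self.n_tn + self.n_fp + self.n_fn


def confusion_from_labels(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    return ConfusionCounts(
        n_tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        n_tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        n_fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        n_fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ValueError("accuracy undefined on empty counts")
    return (c.n_tp + c.n_tn) / c.total


def recall(c: ConfusionCounts) -> float:
    denom = c.n_tp + c.n_fn
    if denom == 0:
        warnings.warn("no positive instances; recall defined as 0")
        return 0.0
    return c.n_tp / denom


def precision(c: ConfusionCounts) -> float:
    denom = c.n_tp + c.n_fp
    if denom == 0:
        warnings.warn("no positive predictions; precision defined as 0")
        return 0.0
    return c.n_tp / denom


def f1_score(c: ConfusionCounts) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, p = recall(c), precision(c)
    if r + p == 0:
        warnings.warn("both recall and precision are 0; F1 defined as 0")
        return 0.0
    return 2 * r * p / (r + p)


def auc(scores, labels) -> float:
    """Area under the empirical ROC curve (Mann–Whitney statistic)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _pairs(y, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y.shape != y_pred.shape:
        raise ValueError("actual and predicted vectors differ in length")
    return y, y_pred


def rmse_as_printed(y, y_pred) -> float:
    """Term-wise ``(1/n) Σ sqrt((y_i − y′_i)²)`` — identical to MAE."""
    y, y_pred = _pairs(y, y_pred)
    return float(np.mean(np.sqrt((y - y_pred) ** 2)))


def rmse_standard(y, y_pred) -> float:
    """Conventional root of the mean squared error."""
    y, y_pred = _pairs(y, y_pred)
    return float(np.sqrt(np.mean((y - y_pred) ** 2)))


def mae(y, y_pred) -> float:
    y, y_pred = _pairs(y, y_pred)
    return float(np.mean(np.abs(y - y_pred)))


def pcc(y, y_pred) -> float:
    """Pearson correlation between actual and predicted values."""
    y, y_pred = _pairs(y, y_pred)
    if y.size < 2:
        raise ValueError("PCC requires at least 2 pairs")
    if np.var(y) == 0 or np.var(y_pred) == 0:
        raise ValueError("PCC undefined for a constant vector")
    return float(pearsonr(y, y_pred).statistic)


def _residual_ratio(y, y_pred) -> float:
    y, y_pred = _pairs(y, y_pred)
    if y.size < 2:
        raise ValueError("variance score requires at least 2 pairs")
    var_y = np.var(y)  # population convention
    if var_y == 0:
        raise ValueError("variance score undefined for constant actuals")
    return float(np.var(y - y_pred) / var_y)


def varscore_as_printed(y, y_pred) -> float:
    """``(1/n)(1 − V(y − y′)/V(y))`` with the 1/n factor applied literally."""
    n = np.asarray(y).size
    return (1.0 - _residual_ratio(y, y_pred)) / n


def explained_variance(y, y_pred) -> float:
    """``1 − V(y − y′)/V(y)``; equals 1 when residual variance is 0."""
    return 1.0 - _residual_ratio(y, y_pred)


def classification_report(y_true, scores, threshold: float = 0.5) -> dict:
    """Accuracy / F1 / AUC block from true labels and positive-class scores."""
    y_pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    c = confusion_from_labels(y_true, y_pred)
    return {
        "accuracy": accuracy(c),
        "recall": recall(c),
        "precision": precision(c),
        "f1": f1_score(c),
        "auc": auc(scores, y_true),
    }


def regression_report(y_true, y_pred) -> dict:
    """RMSE / MAE / PCC / explained-variance block (standard variants)."""
    return {
        "rmse": rmse_standard(y_true, y_pred),
        "mae": mae(y_true, y_pred),
        "pcc": pcc(y_true, y_pred),
        "varscore": explained_variance(y_true, y_pred),
        "variant": "standard",
    }
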