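"""Model evaluation: regression error, the two-line improvement endpoint,
confusion-matrix metrics and ROC/AUC with a paired AUC comparison.

Regression quality is measured by MAE and RMSE between predicted and
true postoperative BCVA (logMAR). The clinical endpoint is binary:
vision counts as improved when it gains at least two chart lines, i.e.
preoperative minus postoperative BCVA >= 0.2 logMAR (logMAR falls as
vision improves). Classifying predicted outcomes against measured ones
gives the confusion table and the printed-formula metrics

    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)
    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    F1          = 2 * sensitivity * precision / (sensitivity + precision)

while the continuous predicted improvement (preop - predicted postop)
swept over thresholds yields the ROC curve and its AUC. Paired AUCs are
compared with DeLong's nonparametric test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .errors import ValidationError

__all__ = [
    "ConfusionTable",
    "MetricsReport",
    "mae",
    "rmse",
    "improvement_label",
    "classify_predictions",
    "confusion_table",
    "confusion_metrics",
    "roc_auc",
    "compare_auc",
    "evaluate_predictions",
    "IMPROVEMENT_THRESHOLD",
]

#: two chart lines, in logMAR
IMPROVEMENT_THRESHOLD = 0.2


def _pairs(y_pred, y_true):
    y_pred = np.asarray(y_pred, dtype=float)
    y_true = np.asarray(y_true, dtype=float)
    if y_pred.shape != y_true.shape or y_pred.ndim != 1 or y_pred.size == 0:
        raise ValidationError("prediction and truth must be equal-length 1-D, non-empty")
    if not (np.all(np.isfinite(y_pred)) and np.all(np.isfinite(y_true))):
        raise ValidationError("predictions and truths must be finite")
    return y_pred, y_true


def mae(y_pred, y_true) -> float:
    """Mean absolute error."""
    y_pred, y_true = _pairs(y_pred, y_true)
    return float(np.mean(np.abs(y_pred - y_true)))


def rmse(y_pred, y_true) -> float:
    """Root mean square error."""
    y_pred, y_true = _pairs(y_pred, y_true)
    return float(np.sqrt(np.mean((y_pred - y_true) ** 2)))


def improvement_label(preop, postop) -> np.ndarray | bool:
    """True when BCVA improved by at least two chart lines (0.2 logMAR)."""
    preop = np.asarray(preop, dtype=float)
    postop = np.asarray(postop, dtype=float)
    if not (np.all(np.isfinite(preop)) and np.all(np.isfinite(postop))):
        raise ValidationError("BCVA values must be finite")
    out = (preop - postop) >= IMPROVEMENT_THRESHOLD
    return bool(out) if out.ndim == 0 else out


def classify_predictions(
    y_pred, y_true, preop, threshold: float = IMPROVEMENT_THRESHOLD
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Turn the regressor's output into endpoint labels.

    Returns ``(pred_labels, true_labels, scores)``: true labels from the
    measured (preop, postop) pair, predicted labels from the measured
    preop and the predicted postop, and the continuous predicted
    improvement ``preop - y_pred`` retained as the ROC score.
    """
    y_pred, y_true = _pairs(y_pred, y_true)
    preop = np.asarray(preop, dtype=float)
    if preop.shape != y_pred.shape:
        raise ValidationError("preop vector must align with predictions")
    scores = preop - y_pred
    return scores >= threshold, (preop - y_true) >= threshold, scores


@dataclass
class ConfusionTable:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_table(pred_labels, true_labels) -> ConfusionTable:
    pred = np.asarray(pred_labels, dtype=bool)
    true = np.asarray(true_labels, dtype=bool)
    if pred.shape != true.shape:
        raise ValidationError("label vectors must align")
    return ConfusionTable(
        tp=int(np.sum(pred & true)),
        fp=int(np.sum(pred & ~true)),
        tn=int(np.sum(~pred & ~true)),
        fn=int(np.sum(~pred & true)),
    )


def confusion_metrics(table: ConfusionTable) -> dict:
    """Precision, sensitivity, accuracy and F1 from the printed formulas.

    Ratios with a zero denominator are reported as None (flagged
    undefined) rather than coerced to 0.
    """
    if table.n == 0:
        raise ValidationError("empty confusion table")
    tp, fp, tn, fn = table.tp, table.fp, table.tn, table.fn
    precision = tp / (tp + fp) if tp + fp > 0 else None
    sensitivity = tp / (tp + fn) if tp + fn > 0 else None
    accuracy = (tp + tn) / table.n
    if precision is not None and sensitivity is not None and precision + sensitivity > 0:
        f1 = 2.0 * sensitivity * precision / (sensitivity + precision)
    else:
        f1 = None
    return {
        "precision": precision,
        "sensitivity": sensitivity,
        "accuracy": accuracy,
        "f1": f1,
    }


def roc_auc(scores, true_labels) -> tuple[float, np.ndarray]:
    """ROC curve and trapezoidal AUC over all score thresholds.

    Equals the Mann-Whitney concordance probability (ties counted half).
    Returns ``(auc, roc_points)`` with roc_points as (FPR, TPR) rows.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(true_labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must align")
    if labels.all() or not labels.any():
        raise ValidationError("AUC undefined: only one class present")
    fpr, tpr, _ = _roc_curve(labels.astype(int), scores)
    return float(_trapezoid_auc(fpr, tpr)), np.column_stack([fpr, tpr])


# ---- DeLong paired AUC comparison --------------------------------------


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_variance(scores: np.ndarray, labels: np.ndarray):
    """Fast DeLong AUC and covariance for k score vectors on shared labels.

    Uses the midrank formulation: per-sample structural components
    V10 (positives) and V01 (negatives) give the AUC covariance matrix
    S10/m + S01/n.
    """
    pos = scores[:, labels]
    neg = scores[:, ~labels]
    m, n = pos.shape[1], neg.shape[1]
    k = scores.shape[0]
    aucs = np.empty(k)
    v10 = np.empty((k, m))
    v01 = np.empty((k, n))
    for r in range(k):
        allr = _midrank(np.concatenate([pos[r], neg[r]]))
        pr = _midrank(pos[r])
        nr = _midrank(neg[r])
        aucs[r] = (allr[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v10[r] = (allr[:m] - pr) / n
        v01[r] = 1.0 - (allr[m:] - nr) / m
    s10 = np.cov(v10) if k > 1 else np.atleast_2d(np.var(v10, ddof=1))
    s01 = np.cov(v01) if k > 1 else np.atleast_2d(np.var(v01, ddof=1))
    return aucs, np.atleast_2d(s10) / m + np.atleast_2d(s01) / n


def compare_auc(scores_a, scores_b, true_labels) -> float:
    """Two-sided DeLong test for paired AUC difference.

    Both score vectors must be computed on the same eyes (paired design);
    identical vectors give p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(true_labels, dtype=bool)
    if a.shape != b.shape or a.shape != labels.shape:
        raise ValidationError("paired scores and labels must align")
    if labels.all() or not labels.any():
        raise ValidationError("AUC comparison undefined: only one class present")
    if np.array_equal(a, b):
        return 1.0
    aucs, cov = _delong_variance(np.vstack([a, b]), labels)
    var = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var <= 1e-16:
        return 1.0 if abs(aucs[0] - aucs[1]) < 1e-12 else 0.0
    z = (aucs[0] - aucs[1]) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


@dataclass
class MetricsReport:
    """Bundle of regression + endpoint metrics for one model's predictions."""

    mae: float
    rmse: float
    precision: float | None
    sensitivity: float | None
    accuracy: float
    f1: float | None
    auc: float
    roc_points: np.ndarray = field(repr=False)
    confusion: ConfusionTable = None

    def __post_init__(self):
        if self.mae > self.rmse + 1e-12:
            raise ValidationError("MAE cannot exceed RMSE")

    def to_dict(self) -> dict:
        return {
            "mae": self.mae,
            "rmse": self.rmse,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "auc": self.auc,
        }


def evaluate_predictions(y_pred, y_true, preop) -> MetricsReport:
    """Full report: regression errors plus improvement-endpoint
    classification metrics and ROC/AUC."""
    pred_lab, true_lab, scores = classify_predictions(y_pred, y_true, preop)
    table = confusion_table(pred_lab, true_lab)
    cm = confusion_metrics(table)
    auc_val, roc_pts = roc_auc(scores, true_lab)
    return MetricsReport(
        mae=mae(y_pred, y_true),
        rmse=rmse(y_pred, y_true),
        precision=cm["precision"],
        sensitivity=cm["sensitivity"],
        accuracy=cm["accuracy"],
        f1=cm["f1"],
        auc=auc_val,
        roc_points=roc_pts,
        confusion=table,
    )
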