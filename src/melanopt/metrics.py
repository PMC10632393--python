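"""Binary classification metrics for the melanoma / non-melanoma task.

The positive class is melanoma. All ratio metrics are computed with exact
rational arithmetic (:class:`fractions.Fraction`) and converted to float at
the end, so printed values agree with hand calculation to machine precision.

Two averaging conventions are exposed: per-class metrics for the melanoma
class (:func:`binary_metrics`) and unweighted macro averages over the two
classes (:func:`macro_metrics`), the convention used by the reference
result tables this package reproduces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "UndefinedMetricError",
    "confusion",
    "binary_metrics",
    "macro_metrics",
    "csi",
    "mcc",
    "roc_curve",
]


class UndefinedMetricError(ZeroDivisionError):
    """Raised when a metric's denominator is zero; names the metric."""

    def __init__(self, metric: str):
        self.metric = metric
        super().__init__(f"metric '{metric}' is undefined (zero denominator)")


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/TN/FP/FN counts; melanoma is the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(true_labels, predicted_labels, positive=1) -> ConfusionMatrix:
    """Count TP/TN/FP/FN from paired label sequences.

    Labels may be any hashable values; ``positive`` marks the melanoma class.
    """
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("true and predicted labels must have equal length")
    if t.size == 0:
        raise ValueError("empty label sequences")
    tpos = t == positive
    ppos = p == positive
    return ConfusionMatrix(
        tp=int(np.sum(tpos & ppos)),
        tn=int(np.sum(~tpos & ~ppos)),
        fp=int(np.sum(~tpos & ppos)),
        fn=int(np.sum(tpos & ~ppos)),
    )


def _frac(num: int, den: int, metric: str) -> Fraction:
    if den == 0:
        raise UndefinedMetricError(metric)
    return Fraction(num, den)


def binary_metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy, precision, recall, F-measure, sensitivity, specificity.

    Precision/recall/F are for the positive (melanoma) class; sensitivity is
    the positive-class recall and specificity = TN / (TN + FP).
    """
    acc = _frac(cm.tp + cm.tn, cm.total, "accuracy")
    prec = _frac(cm.tp, cm.tp + cm.fp, "precision")
    rec = _frac(cm.tp, cm.tp + cm.fn, "recall")
    if prec + rec == 0:
        raise UndefinedMetricError("f_measure")
    f = 2 * prec * rec / (prec + rec)
    spec = _frac(cm.tn, cm.tn + cm.fp, "specificity")
    return {
        "accuracy": float(acc),
        "precision": float(prec),
        "recall": float(rec),
        "f_measure": float(f),
        "sensitivity": float(rec),
        "specificity": float(spec),
    }


def macro_metrics(cm: ConfusionMatrix) -> dict:
    """Unweighted two-class macro precision / recall / F-measure.

    The negative class's precision and recall are the positive-class formulas
    with the class roles swapped (TP<->TN, FP<->FN).
    """
    prec_pos = _frac(cm.tp, cm.tp + cm.fp, "macro_precision")
    rec_pos = _frac(cm.tp, cm.tp + cm.fn, "macro_recall")
    prec_neg = _frac(cm.tn, cm.tn + cm.fn, "macro_precision")
    rec_neg = _frac(cm.tn, cm.tn + cm.fp, "macro_recall")
    if prec_pos + rec_pos == 0 or prec_neg + rec_neg == 0:
        raise UndefinedMetricError("macro_f_measure")
    f_pos = 2 * prec_pos * rec_pos / (prec_pos + rec_pos)
    f_neg = 2 * prec_neg * rec_neg / (prec_neg + rec_neg)
    return {
        "macro_precision": float((prec_pos + prec_neg) / 2),
        "macro_recall": float((rec_pos + rec_neg) / 2),
        "macro_f_measure": float((f_pos + f_neg) / 2),
    }


def csi(cm: ConfusionMatrix) -> float:
    """Classification Success Index: PPV + TPR - 1, in [-1, 1]."""
    ppv = _frac(cm.tp, cm.tp + cm.fp, "csi")
    tpr = _frac(cm.tp, cm.tp + cm.fn, "csi")
    return float(ppv + tpr - 1)


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient in [-1, 1].

    Standard symmetric form: (TP*TN - FP*FN) / sqrt of the product of the
    four marginal totals.
    """
    m1 = cm.tp + cm.fp
    m2 = cm.tp + cm.fn
    m3 = cm.tn + cm.fp
    m4 = cm.tn + cm.fn
    if 0 in (m1, m2, m3, m4):
        raise UndefinedMetricError("mcc")
    num = cm.tp * cm.tn - cm.fp * cm.fn
    return float(num / math.sqrt(m1 * m2 * m3 * m4))


def roc_curve(scores, true_labels, positive=1):
    """ROC points and trapezoid AUC from positive-class scores.

    The decision threshold is swept over the unique score values (predict
    positive when score >= threshold); the conventional (0, 0) and (1, 1)
    endpoints are included.

    Returns
    -------
    fpr, tpr : ndarray
        Curve points sorted by increasing FPR.
    auc : float
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(true_labels) == positive
    if s.shape != t.shape or s.size == 0:
        raise ValueError("scores and labels must be equal-length and non-empty")
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("scores must lie in [0, 1]")
    n_pos = int(t.sum())
    n_neg = int(t.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("roc_curve")
    thresholds = np.unique(s)[::-1]
    fpr = [0.0]
    tpr = [0.0]
    for thr in thresholds:
        pred = s >= thr
        tpr.append(float(np.sum(pred & t)) / n_pos)
        fpr.append(float(np.sum(pred & ~t)) / n_neg)
    if fpr[-1] != 1.0 or tpr[-1] != 1.0:
        fpr.append(1.0)
        tpr.append(1.0)
    fpr = np.asarray(fpr)
    tpr = np.asarray(tpr)
    order = np.lexsort((tpr, fpr))
    fpr, tpr = fpr[order], tpr[order]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc
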