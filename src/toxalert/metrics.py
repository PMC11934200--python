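"""Binary-classification metrics implemented from the confusion matrix up.

All scalar scores (precision, recall, F1, accuracy, Matthews correlation,
Cohen's kappa) derive from TP/FP/TN/FN counts; ROC-AUC uses the
rank/Mann–Whitney formulation (probability that a random positive outscores
a random negative, ties counted ½).  Degenerate denominators return 0 by
convention, with a logged warning, so that reports are always total.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

#: Probability at or above which a classifier output predicts class 1.
DEFAULT_THRESHOLD = 0.5


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _as_binary(values: Sequence[int], name: str) -> np.ndarray:
    arr = np.asarray(values)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return arr.astype(int)


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Exact TP/FP/TN/FN counts from two equal-length binary sequences."""
    t = _as_binary(y_true, "y_true")
    p = _as_binary(y_pred, "y_pred")
    if t.shape != p.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        fp=int(np.sum((t == 0) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("%s has zero denominator; returning 0 by convention", what)
        return 0.0
    return num / den


def precision(c: ConfusionCounts) -> float:
    return _safe_div(c.tp, c.tp + c.fp, "precision")


def recall(c: ConfusionCounts) -> float:
    return _safe_div(c.tp, c.tp + c.fn, "recall")


def accuracy(c: ConfusionCounts) -> float:
    return _safe_div(c.tp + c.tn, c.total, "accuracy")


def f1_score(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0 <= p <= 1 and 0 <= r <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    return _safe_div(2 * p * r, p + r, "F1")


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient.

    (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)); informative under
    class imbalance because all four confusion cells enter symmetrically.
    Any zero factor makes the score 0 by convention.
    """
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return _safe_div(tp * tn - fp * fn, denom, "MCC")


def cohen_kappa(c: ConfusionCounts) -> float:
    """Cohen's kappa: observed agreement corrected for chance agreement."""
    n = c.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    po = (c.tp + c.tn) / n
    pe = ((c.tp + c.fp) * (c.tp + c.fn) + (c.tn + c.fn) * (c.tn + c.fp)) / (n * n)
    if pe == 1.0:
        logger.warning("kappa chance agreement is 1; returning 0 by convention")
        return 0.0
    return (po - pe) / (1 - pe)


def roc_auc(scores: Sequence[float], y_true: Sequence[int]) -> float:
    """Area under the ROC curve via mid-ranks (Mann–Whitney U / (n₊ n₋))."""
    y = _as_binary(y_true, "y_true")
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC-AUC requires both classes present")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


@dataclass
class MetricsReport:
    task: str
    precision: float
    recall: float
    f1: float
    accuracy: float
    mcc: float
    kappa: float
    roc_auc: float
    counts: ConfusionCounts | None = None


def evaluate(scores: Sequence[float], y_true: Sequence[int], task: str = "",
             threshold: float = DEFAULT_THRESHOLD) -> MetricsReport:
    """Full scalar report from class-1 probabilities and true labels."""
    y_pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    c = confusion(y_true, y_pred)
    p, r = precision(c), recall(c)
    return MetricsReport(
        task=task,
        precision=p,
        recall=r,
        f1=f1_score(p, r),
        accuracy=accuracy(c),
        mcc=mcc(c),
        kappa=cohen_kappa(c),
        roc_auc=roc_auc(scores, y_true),
        counts=c,
    )


def reports_to_csv(reports: Sequence[MetricsReport], path: str | Path) -> None:
    """One row per task: Precision, Recall, F1, Accuracy, MCC (plus extras)."""
    import pandas as pd

    rows = [{
        "Task": r.task,
        "Precision": r.precision,
        "Recall": r.recall,
        "F1": r.f1,
        "Accuracy": r.accuracy,
        "MCC": r.mcc,
        "Kappa": r.kappa,
        "ROC-AUC": r.roc_auc,
    } for r in reports]
    pd.DataFrame(rows).to_csv(path, index=False)
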