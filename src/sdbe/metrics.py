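"""Binary-classification performance metrics from merged out-of-fold predictions.

Six metrics drive the pipeline: accuracy, recall, F1, false positive rate,
Matthews correlation coefficient (MCC) and ROC AUC. MCC and AUC are the two
candidates for the "metric object" whose before/after-deletion differences
steer the backward-elimination sort; both are robust on strongly imbalanced
phenotypes, which is why they matter for tumor-vs-normal cohorts where
positives outnumber negatives roughly ten to one.

Conventions: the positive class is 1 (tumor). Every ratio with a zero
denominator returns 0 so that elimination traces stay finite. AUC uses the
tie-aware rank (Mann-Whitney) formulation: the probability that a random
positive scores above a random negative, ties counting one half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "MetricVector",
    "confusion_counts",
    "mcc",
    "basic_metrics",
    "roc_auc",
    "metric_vector",
    "METRIC_NAMES",
]

#: names of the metrics a MetricVector carries, in canonical report order
METRIC_NAMES = ("acc", "re", "pr", "f1", "fpr", "mcc", "roc_auc")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN counts; the four partition the evaluated samples."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricVector:
    """The six performance metrics plus precision (needed by F1)."""

    acc: float
    re: float
    pr: float
    f1: float
    fpr: float
    mcc: float
    roc_auc: float

    def __getitem__(self, name: str) -> float:
        if name not in METRIC_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Count TP/FP/FN/TN by comparing predictions with the tested labels."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or len(y_true) == 0:
        raise ValueError("y_true and y_pred must be equal-length nonempty 1-D vectors")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); 0 when any
    factor of the denominator vanishes.
    """
    num = c.tp * c.tn - c.fp * c.fn
    den = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if den == 0:
        return 0.0
    return num / math.sqrt(den)


def basic_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, recall, precision, F1 and false positive rate.

    0/0 forms return 0 by convention (e.g. precision with no positive
    predictions).
    """
    acc = _safe_div(c.tn + c.tp, c.total)
    re = _safe_div(c.tp, c.tp + c.fn)
    pr = _safe_div(c.tp, c.tp + c.fp)
    f1 = _safe_div(2.0 * pr * re, pr + re)
    fpr = _safe_div(c.fp, c.fp + c.tn)
    return {"acc": acc, "re": re, "pr": pr, "f1": f1, "fpr": fpr}


def roc_auc(y_true, scores) -> float:
    """Rank-based area under the ROC curve.

    Equals the probability that a uniformly drawn positive sample receives a
    higher score than a uniformly drawn negative one, ties counting 1/2
    (midrank Mann-Whitney formulation).
    """
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape or y_true.ndim != 1:
        raise ValueError("y_true and scores must be equal-length 1-D vectors")
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(scores)  # midranks handle ties
    rank_sum_pos = float(ranks[y_true == 1].sum())
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def metric_vector(y_true, y_pred, scores) -> MetricVector:
    """All metrics from merged out-of-fold labels, predictions and scores."""
    c = confusion_counts(y_true, y_pred)
    basics = basic_metrics(c)
    return MetricVector(mcc=mcc(c), roc_auc=roc_auc(y_true, scores), **basics)
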