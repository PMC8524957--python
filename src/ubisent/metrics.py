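"""Confusion counts and classification metrics.

The five sentence-level evaluation indicators are

    accuracy    = (T_p + T_n) / N
    precision   = T_p / (T_p + F_p)
    recall      = T_p / (T_p + F_n)
    specificity = T_n / (T_n + F_p)
    F1          = 2 * precision * recall / (precision + recall)

where the positive class is "states an E3-substrate interaction".
Ratios with a zero denominator are reported as NaN (undefined), never as
0, so they cannot silently corrupt averages over folds.  ROC AUC is the
rank-based (Mann-Whitney) area, ties counted half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = ["ConfusionCounts", "MetricsReport", "confusion", "compute_metrics", "roc_auc"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; tp + tn + fp + fn = n."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The five indicators plus optional ROC AUC; NaN marks undefined."""

    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    roc_auc: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
            "roc_auc": self.roc_auc,
        }

    def rounded(self, digits: int = 3) -> dict[str, float]:
        """Half-away-from-zero rounding, as printed report tables use."""

        def r(x: float) -> float:
            if math.isnan(x):
                return x
            q = 10.0**digits
            return math.floor(abs(x) * q + 0.5) / q * (1 if x >= 0 else -1)

        return {k: r(v) for k, v in self.as_dict().items()}


def confusion(true_labels, predicted_labels) -> ConfusionCounts:
    """Count tp/tn/fp/fn for binary labels (1 = interaction-stating)."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    if t.size == 0:
        raise ValueError("empty label vectors")
    for arr in (t, p):
        if not np.isin(arr, [0, 1]).all():
            raise ValueError("labels must be binary 0/1")
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def compute_metrics(c: ConfusionCounts, roc_auc: float = math.nan) -> MetricsReport:
    """Exact formula application over confusion counts."""
    if c.n == 0:
        raise ValueError("cannot compute metrics over zero sentences")
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = math.nan
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return MetricsReport(
        accuracy=(c.tp + c.tn) / c.n,
        precision=precision,
        recall=recall,
        specificity=_ratio(c.tn, c.tn + c.fp),
        f1=f1,
        roc_auc=roc_auc,
    )


def roc_auc(true_labels, scores) -> float:
    """Rank-based ROC AUC (ties counted half); NaN if one class absent."""
    t = np.asarray(true_labels, dtype=np.int64)
    s = np.asarray(scores, dtype=np.float64)
    if t.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    if np.unique(t).size < 2:
        return math.nan
    return float(roc_auc_score(t, s))
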