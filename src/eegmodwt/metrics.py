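"""Binary-classification evaluation metrics and a 2x2 contingency test.

The patient (AD) class is the positive class throughout: TP counts
correctly identified patients, TN correctly identified controls.
Metrics whose denominator is zero are reported as NaN rather than 0,
so that a degenerate fold is visible instead of silently pessimistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "classification_metrics",
    "auc_rank",
    "chi_square_2x2",
    "METRIC_NAMES",
]

METRIC_NAMES = ("accuracy", "auc", "f_measure", "specificity", "recall", "precision")


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion-matrix cell counts with the patient class positive."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for v in (self.tp, self.fp, self.tn, self.fn):
            if v < 0:
                raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ValueError("empty confusion table")

    @classmethod
    def from_labels(cls, y_true, y_pred, positive) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos_t = y_true == positive
        pos_p = y_pred == positive
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
        )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall (sensitivity), specificity, F-measure.

    F-measure is the harmonic mean of precision and recall; it is NaN
    when either is undefined or both are zero.
    """
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f = float("nan")
    else:
        f = 2 * precision * recall / (precision + recall)
    return {
        "accuracy": _ratio(c.tp + c.tn, c.tp + c.fp + c.tn + c.fn),
        "precision": precision,
        "recall": recall,
        "specificity": _ratio(c.tn, c.fp + c.tn),
        "f_measure": f,
    }


def auc_rank(scores, y_true, positive) -> float:
    """Area under the ROC curve by the rank-sum (Mann-Whitney) formula.

    ``AUC = (sum of positive-class midranks - M(M+1)/2) / (M * N)`` with
    M positives and N negatives; tied scores take midranks, so the value
    equals the probability that a random positive outscores a random
    negative, ties counting one half.
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(y_true) == positive
    m = int(pos.sum())
    n_neg = int((~pos).sum())
    if m == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(scores)  # midranks for ties
    return float((ranks[pos].sum() - m * (m + 1) / 2) / (m * n_neg))


def chi_square_2x2(table) -> float:
    """Pearson chi-square statistic of a 2x2 table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = t.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("degenerate margin in contingency table")
    expected = np.outer(row, col) / n
    return float(((t - expected) ** 2 / expected).sum())
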