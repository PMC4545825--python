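"""Confusion-matrix statistics, the F-beta family, ROC curves and AUC.

Sensitivity, specificity and precision use the standard forms
Se = TP/(TP+FN), Sp = TN/(TN+FP), P = TP/(TP+FP).  Undefined ratios
(zero denominator) are returned as NaN rather than raising, so
evaluation loops over degenerate score slices stay total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skm


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(pred: Sequence[bool], actual: Sequence[bool]) -> ConfusionCounts:
    p = np.asarray(pred, dtype=bool)
    a = np.asarray(actual, dtype=bool)
    if p.shape != a.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {a.shape}")
    return ConfusionCounts(
        tp=int(np.sum(p & a)),
        fp=int(np.sum(p & ~a)),
        tn=int(np.sum(~p & ~a)),
        fn=int(np.sum(~p & a)),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def sensitivity(c: ConfusionCounts) -> float:
    """True positive rate TP/(TP+FN); NaN when no actual positives."""
    return _ratio(c.tp, c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """True negative rate TN/(TN+FP); NaN when no actual negatives."""
    return _ratio(c.tn, c.tn + c.fp)


def precision(c: ConfusionCounts) -> float:
    """Positive predictive value TP/(TP+FP); NaN when nothing predicted positive."""
    return _ratio(c.tp, c.tp + c.fp)


def fbeta(precision_: float, recall: float, beta: float) -> float:
    """F_beta = (1+b^2) P R / (b^2 P + R); 0 when P = R = 0 by convention."""
    if not (0 <= precision_ <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    b2 = beta * beta
    denom = b2 * precision_ + recall
    if denom == 0:
        return 0.0
    return (1 + b2) * precision_ * recall / denom


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> pd.DataFrame:
    """ROC curve by descending-score sweep, tied scores grouped.

    Returns a DataFrame with columns fpr, tpr, threshold; the curve
    starts at (0, 0) (threshold +inf) and ends at (1, 1).
    """
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("roc_curve requires both classes present")
    fpr, tpr, thr = _skm.roc_curve(y, np.asarray(scores, dtype=float),
                                   drop_intermediate=False)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def auc(curve: pd.DataFrame) -> float:
    """Trapezoidal area under a ROC curve frame."""
    return float(np.trapezoid(curve["tpr"].to_numpy(), curve["fpr"].to_numpy()))


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    return auc(roc_curve(scores, labels))
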