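"""Confusion counts, accuracy / sensitivity / specificity / MCC, ROC and AUC.

Accuracy    = (TP + TN) / (TP + FP + TN + FN)
Sensitivity = TP / (TP + FN)
Specificity = TN / (TN + FP)
MCC         = (TP*TN - FP*FN) / sqrt((TP+FP)(TN+FN)(TP+FN)(TN+FP))

MCC lies in [-1, 1]; +1 is perfect prediction, -1 perfect anti-correlation,
0 the expectation of random guessing.  When any marginal of the confusion
matrix is zero the MCC denominator vanishes; the value is then reported as
0 with ``mcc_undefined`` flagged, a common convention.

ROC curves are built from continuous decision values (threshold sweep with
tied scores grouped), and AUC by the trapezoid rule, which equals the
normalized Mann-Whitney U statistic in the absence of ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN tallies for ±1 labels."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Percent-scale accuracy/sensitivity/specificity plus MCC."""

    counts: ConfusionCounts
    accuracy: float
    sensitivity: float
    specificity: float
    mcc: float
    mcc_undefined: bool = False

    def as_dict(self) -> dict:
        return {
            "tp": self.counts.tp, "fp": self.counts.fp,
            "tn": self.counts.tn, "fn": self.counts.fn,
            "accuracy": round(self.accuracy, 2),
            "sensitivity": round(self.sensitivity, 2),
            "specificity": round(self.specificity, 2),
            "mcc": round(self.mcc, 4),
            "mcc_undefined": self.mcc_undefined,
        }


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Tally TP/FP/TN/FN; labels must be +1/-1 and of equal length >= 1."""
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape or t.ndim != 1 or len(t) == 0:
        raise ValueError("y_true and y_pred must be equal-length, nonempty")
    for arr, name in ((t, "y_true"), (p, "y_pred")):
        if not np.all(np.isin(arr, (-1, 1))):
            raise ValueError(f"{name} contains labels outside {{+1, -1}}")
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        fp=int(np.sum((t == -1) & (p == 1))),
        tn=int(np.sum((t == -1) & (p == -1))),
        fn=int(np.sum((t == 1) & (p == -1))),
    )


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy, sensitivity, specificity (percent) and MCC from counts."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if counts.n == 0:
        raise ValueError("empty confusion matrix")
    accuracy = 100.0 * (tp + tn) / counts.n
    sensitivity = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    specificity = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    denom = (tp + fp) * (tn + fn) * (tp + fn) * (tn + fp)
    if denom == 0:
        mcc, undefined = 0.0, True
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
        undefined = False
    return MetricsReport(
        counts=counts,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        mcc=mcc,
        mcc_undefined=undefined,
    )


def roc_points(
    decision_vals: Sequence[float], y_true: Sequence[int]
) -> list[tuple[float, float]]:
    """(FPR, TPR) points of the threshold sweep, from (0,0) to (1,1).

    Tied decision values are grouped (one point per distinct threshold).
    """
    y = np.asarray(y_true)
    s = np.asarray(decision_vals, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = _sk_roc_curve(y, s, pos_label=1, drop_intermediate=False)
    return [(float(x), float(t)) for x, t in zip(fpr, tpr)]


def auc(points: Sequence[tuple[float, float]]) -> float:
    """Area under an ROC polyline by the trapezoid rule."""
    pts = sorted(points)
    x = np.array([p[0] for p in pts])
    t = np.array([p[1] for p in pts])
    return float(np.trapezoid(t, x))


def evaluate(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    decision_vals: Sequence[float] | None = None,
) -> dict:
    """Full evaluation dict: counts, the four metrics, and ROC/AUC if scores given."""
    rep = metrics(confusion(y_true, y_pred)).as_dict()
    if decision_vals is not None:
        pts = roc_points(decision_vals, y_true)
        rep["roc"] = pts
        rep["auc"] = round(auc(pts), 4)
    return rep
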