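"""Diagnostic classification statistics.

ROC curves with one vertex per distinct score (tie groups get half credit in
the trapezoidal AUC, which then equals the Mann-Whitney statistic
U/(n1*n2)), Youden-index binarization with ties broken toward higher
sensitivity, confusion-matrix summaries, and the two-point trapezoidal AUC
identity used for binary raters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

Orientation = Literal["lower_is_positive", "higher_is_positive"]


@dataclass
class RocCurve:
    """ROC polyline from (0,0) to (1,1), one vertex per distinct score."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray  # cutoff per vertex; nan at the (0,0) origin
    orientation: Orientation

    def __post_init__(self) -> None:
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("fpr/tpr must be non-decreasing")
        if not (self.fpr[0] == 0 and self.tpr[0] == 0 and self.fpr[-1] == 1 and self.tpr[-1] == 1):
            raise ValueError("curve must run from (0,0) to (1,1)")


@dataclass
class ClassificationSummary:
    accuracy_pct: float
    sensitivity_pct: float
    specificity_pct: float
    youden: float  # J = sensitivity + specificity - 1, as proportions
    counts: tuple[int, int, int, int]  # (tp, fn, tn, fp)
    auc: float | None = None
    cutoff: float | None = None


def _as_positive(labels: Sequence) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "UOS":
        return y == "PD"
    return y.astype(bool)


def roc_curve(scores: Sequence[float], labels: Sequence,
              orientation: Orientation = "lower_is_positive") -> RocCurve:
    """ROC curve of a continuous marker against PD/HC labels.

    orientation="lower_is_positive" treats score <= cutoff as PD-positive
    (volumes and the composite fall with disease); "higher_is_positive"
    treats score >= cutoff as positive.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    y = _as_positive(labels)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ascending = orientation == "lower_is_positive"
    order = np.argsort(scores if ascending else -scores, kind="stable")
    s_sorted, y_sorted = scores[order], y[order]
    distinct = np.nonzero(np.diff(s_sorted))[0]
    group_ends = np.concatenate([distinct, [len(s_sorted) - 1]])
    tp_cum = np.cumsum(y_sorted)[group_ends]
    fp_cum = np.cumsum(~y_sorted)[group_ends]
    fpr = np.concatenate([[0.0], fp_cum / n_neg])
    tpr = np.concatenate([[0.0], tp_cum / n_pos])
    thresholds = np.concatenate([[np.nan], s_sorted[group_ends]])
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, orientation=orientation)


def auc_trapezoid(curve: RocCurve) -> float:
    """Trapezoidal AUC; equals Mann-Whitney U/(n1 n2) with tie half-credit."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def auc_of_scores(scores: Sequence[float], labels: Sequence,
                  orientation: Orientation = "lower_is_positive") -> float:
    return auc_trapezoid(roc_curve(scores, labels, orientation))


def youden_optimal_cutoff(curve: RocCurve) -> tuple[float, float]:
    """(cutoff, J) maximizing J = tpr - fpr; ties favour higher sensitivity."""
    j = curve.tpr - curve.fpr
    best = 0
    for i in range(1, len(j)):
        if j[i] > j[best] + 1e-15 or (
            abs(j[i] - j[best]) <= 1e-15 and curve.tpr[i] > curve.tpr[best]
        ):
            best = i
    cutoff = float(curve.thresholds[best]) if best > 0 else float(curve.thresholds[-1])
    return cutoff, float(j[best])


def confusion_summary(tp: int, fn: int, tn: int, fp: int) -> ClassificationSummary:
    """Sensitivity/specificity/accuracy (%) and Youden J from a 2x2 table."""
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("counts must be nonnegative")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both true classes must be nonempty")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / (tp + fn + tn + fp)
    return ClassificationSummary(
        accuracy_pct=100.0 * acc, sensitivity_pct=100.0 * sens,
        specificity_pct=100.0 * spec, youden=sens + spec - 1.0,
        counts=(tp, fn, tn, fp),
    )


def binary_rating_auc(sensitivity_pct: float, specificity_pct: float) -> float:
    """AUC of a binary rater: two-point trapezoid (sens + spec)/200."""
    for v in (sensitivity_pct, specificity_pct):
        if not 0.0 <= v <= 100.0:
            raise ValueError("sensitivity/specificity must be in [0, 100]")
    return (sensitivity_pct + specificity_pct) / 200.0


def counts_from_rates(sensitivity_pct: float, specificity_pct: float,
                      n_pos: int, n_neg: int) -> tuple[int, int, int, int]:
    """Reconstruct (tp, fn, tn, fp) from printed rates and group sizes."""
    tp = int(round(sensitivity_pct / 100.0 * n_pos))
    tn = int(round(specificity_pct / 100.0 * n_neg))
    return tp, n_pos - tp, tn, n_neg - tn


def classify_measure(scores: Sequence[float], labels: Sequence,
                     orientation: Orientation = "lower_is_positive") -> ClassificationSummary:
    """Full marker evaluation: ROC/AUC, Youden cutoff, confusion at the cutoff."""
    curve = roc_curve(scores, labels, orientation)
    auc = auc_trapezoid(curve)
    cutoff, _ = youden_optimal_cutoff(curve)
    scores = np.asarray(scores, dtype=float)
    y = _as_positive(labels)
    pred = scores <= cutoff if orientation == "lower_is_positive" else scores >= cutoff
    tp = int((pred & y).sum())
    fn = int((~pred & y).sum())
    tn = int((~pred & ~y).sum())
    fp = int((pred & ~y).sum())
    summary = confusion_summary(tp, fn, tn, fp)
    summary.auc = auc
    summary.cutoff = cutoff
    return summary
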