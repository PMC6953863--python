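"""Evaluation surface: confusion matrix, CCR, minimum sensitivity, ROC/PR.

All metrics are reported as fractions in [0, 1]; percentage formatting is a
presentation concern.  Class order in the confusion matrix is fixed as
(treated = 1, untreated = 0), rows = true class, columns = predicted class.

* CCR (correct classification rate): trace of the confusion matrix over N.
* MS (minimum sensitivity): the smaller per-class recall; 0 means one class
  was completely misclassified.  On imbalanced cohorts MS guards the
  minority (untreated) class where CCR alone can mislead.
* AUC: trapezoidal area under the ROC built by sweeping all distinct score
  thresholds, grouping tied scores into a single step; numerically equal to
  the tie-corrected Mann-Whitney statistic.
* PR-AUC: trapezoidal area under the precision-recall curve with the same
  threshold convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "ccr",
    "min_sensitivity",
    "auc",
    "roc_points",
    "pr_points_and_auc",
    "compute_report",
]

#: Fixed class order: positive (treated) first.
CLASS_ORDER = (1, 0)


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts, rows = true class, columns = predicted, order (1, 0)."""

    counts: tuple[tuple[int, int], tuple[int, int]]

    def __post_init__(self):
        arr = np.asarray(self.counts)
        if arr.shape != (2, 2):
            raise ValueError("confusion matrix must be 2x2")
        if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("confusion matrix entries must be non-negative integers")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts)

    @property
    def n(self) -> int:
        return int(self.array.sum())

    @property
    def class_totals(self) -> np.ndarray:
        """True-class row totals, order (treated, untreated)."""
        return self.array.sum(axis=1)


def _check_labels(values, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 labels")
    return arr.astype(int)


def confusion_matrix(y_true, y_pred) -> ConfusionMatrix:
    """Tally predictions against truth under the fixed (treated, untreated) order."""
    t = _check_labels(y_true, "true labels")
    p = _check_labels(y_pred, "predicted labels")
    if len(t) != len(p):
        raise ValueError("label vectors must have equal length")
    counts = tuple(
        tuple(int(np.sum((t == ci) & (p == cj))) for cj in CLASS_ORDER) for ci in CLASS_ORDER
    )
    return ConfusionMatrix(counts)


def ccr(cm: ConfusionMatrix) -> float:
    """Correct classification rate: diagonal sum over N."""
    if cm.n == 0:
        raise ValueError("CCR undefined for an empty confusion matrix")
    return float(np.trace(cm.array)) / cm.n


def min_sensitivity(cm: ConfusionMatrix) -> float:
    """Minimum over classes of the per-class recall n_jj / N_j."""
    totals = cm.class_totals
    if (totals == 0).any():
        raise ValueError("minimum sensitivity undefined: a class has no true instances")
    sens = np.diag(cm.array) / totals
    return float(sens.min())


def sensitivities(cm: ConfusionMatrix) -> tuple[float, float]:
    """(treated, untreated) per-class recalls."""
    totals = cm.class_totals
    if (totals == 0).any():
        raise ValueError("sensitivity undefined: a class has no true instances")
    d = np.diag(cm.array) / totals
    return float(d[0]), float(d[1])


def _check_scores(y_true, scores) -> tuple[np.ndarray, np.ndarray]:
    t = _check_labels(y_true, "true labels")
    s = np.asarray(scores, dtype=float)
    if len(t) != len(s):
        raise ValueError("labels and scores must have equal length")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    return t, s


def _roc_curve(t: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Tie-grouped cumulative TPR/FPR, starting at (0, 0)."""
    order = np.argsort(-s, kind="stable")
    t = t[order]
    s = s[order]
    # last index of each tie group
    step = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tp = np.cumsum(t)[step]
    fp = np.cumsum(1 - t)[step]
    P = t.sum()
    N = len(t) - P
    tpr = np.r_[0.0, tp / P]
    fpr = np.r_[0.0, fp / N]
    return fpr, tpr


def roc_points(y_true, scores) -> list[tuple[float, float]]:
    """(FPR, TPR) points from (0,0) to (1,1), monotone in both coordinates."""
    t, s = _check_scores(y_true, scores)
    if len(np.unique(t)) < 2:
        raise ValueError("ROC requires both classes among the true labels")
    fpr, tpr = _roc_curve(t, s)
    return list(zip(fpr.tolist(), tpr.tolist()))


def auc(y_true, scores) -> float:
    """Trapezoidal ROC area; equals the tie-corrected Mann-Whitney statistic."""
    t, s = _check_scores(y_true, scores)
    if len(np.unique(t)) < 2:
        raise ValueError("AUC requires both classes among the true labels")
    fpr, tpr = _roc_curve(t, s)
    return float(np.trapezoid(tpr, fpr))


def pr_points_and_auc(y_true, scores) -> tuple[list[tuple[float, float]], float]:
    """Precision/recall at each threshold step plus the trapezoidal PR area.

    Points are (recall, precision) in increasing recall, prefixed with a
    (0, first precision) anchor so the trapezoid is well defined.
    """
    t, s = _check_scores(y_true, scores)
    P = int(t.sum())
    if P == 0:
        raise ValueError("precision-recall requires at least one positive instance")
    order = np.argsort(-s, kind="stable")
    ts = t[order]
    ss = s[order]
    step = np.r_[np.nonzero(np.diff(ss))[0], len(ss) - 1]
    tp = np.cumsum(ts)[step]
    predicted_pos = step + 1
    recall = tp / P
    precision = tp / predicted_pos
    points = [(0.0, float(precision[0]))] + list(
        zip(recall.tolist(), precision.tolist())
    )
    r = np.array([p[0] for p in points])
    q = np.array([p[1] for p in points])
    return points, float(np.trapezoid(q, r))


@dataclass
class MetricsReport:
    """Full per-model evaluation: CCR, per-class sensitivities, MS, AUC, PR-AUC."""

    ccr: float
    sensitivity_treated: float
    sensitivity_untreated: float
    ms: float
    auc: float
    pr_auc: float
    confusion: ConfusionMatrix
    roc: list[tuple[float, float]] = field(default_factory=list, repr=False)
    pr: list[tuple[float, float]] = field(default_factory=list, repr=False)
    n_connections: int | None = None

    def to_dict(self) -> dict:
        return {
            "ccr": self.ccr,
            "sensitivity_treated": self.sensitivity_treated,
            "sensitivity_untreated": self.sensitivity_untreated,
            "ms": self.ms,
            "auc": self.auc,
            "pr_auc": self.pr_auc,
            "confusion": [list(r) for r in self.confusion.counts],
            "n_connections": self.n_connections,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def compute_report(
    y_true, scores, threshold: float = 0.5, n_connections: int | None = None
) -> MetricsReport:
    """Evaluate probabilistic scores: threshold for the confusion matrix, sweep for ROC/PR."""
    t, s = _check_scores(y_true, scores)
    y_pred = (s >= threshold).astype(int)
    cm = confusion_matrix(t, y_pred)
    s_t, s_u = sensitivities(cm)
    pr_pts, pr_area = pr_points_and_auc(t, s)
    return MetricsReport(
        ccr=ccr(cm),
        sensitivity_treated=s_t,
        sensitivity_untreated=s_u,
        ms=min(s_t, s_u),
        auc=auc(t, s),
        pr_auc=pr_area,
        confusion=cm,
        roc=roc_points(t, s),
        pr=pr_pts,
        n_connections=n_connections,
    )
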