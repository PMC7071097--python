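"""Classification metrics, ROC analysis, threshold optimization, overlays.

Accuracy, sensitivity (recall of the pathological class) and specificity are
computed from the confusion counts; the ROC curve sweeps the decision
threshold over the committee probabilities and its area (AUC, trapezoidal
rule) equals the probability that a random pathological patch outscores a
random healthy one (ties counted half).  The operating threshold ``delta``
is chosen on validation data at the sensitivity/specificity balance point
(minimum |sens - spec|; Youden's J is available as an alternative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class RocCurve:
    """ROC points ordered by descending threshold, plus trapezoidal AUC."""

    thresholds: np.ndarray
    sensitivity: np.ndarray  # TPR per threshold
    one_minus_specificity: np.ndarray  # FPR per threshold
    auc: float


def confusion(labels_true, labels_pred) -> ConfusionCounts:
    """Confusion counts for binary labels (1 = pathological)."""
    y = np.asarray(labels_true, dtype=int)
    p = np.asarray(labels_pred, dtype=int)
    if y.size == 0:
        raise ValueError("cannot evaluate an empty label set")
    if y.shape != p.shape:
        raise ValueError("label vectors differ in length")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def metrics_from_counts(c: ConfusionCounts) -> dict:
    """Accuracy, sensitivity, specificity; degenerate ratios become NaN."""
    out = {"accuracy": (c.tp + c.tn) / c.total}
    if c.tp + c.fn == 0:
        warnings.warn("no positive ground-truth samples: sensitivity undefined")
        out["sensitivity"] = float("nan")
    else:
        out["sensitivity"] = c.tp / (c.tp + c.fn)
    if c.tn + c.fp == 0:
        warnings.warn("no negative ground-truth samples: specificity undefined")
        out["specificity"] = float("nan")
    else:
        out["specificity"] = c.tn / (c.tn + c.fp)
    return out


def roc_auc(prob, labels_true) -> RocCurve:
    """ROC curve over the unique score thresholds + trapezoidal AUC.

    Requires both classes to be present.  The AUC equals the
    Mann-Whitney rank statistic (random positive outranks random negative,
    ties half) to within floating tolerance.
    """
    prob = np.asarray(prob, dtype=float)
    y = np.asarray(labels_true, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, prob)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(
        thresholds=np.clip(thr, 0.0, 1.0),
        sensitivity=tpr,
        one_minus_specificity=fpr,
        auc=auc,
    )


def optimal_delta(roc: RocCurve, criterion: str = "balance") -> float:
    """Operating threshold from a validation ROC curve.

    ``"balance"`` (default) minimizes |sensitivity - specificity|, breaking
    ties toward higher sensitivity — the trade-off at which reported
    sensitivity and specificity nearly coincide.  ``"youden"`` maximizes
    sensitivity + specificity - 1.
    """
    sens = roc.sensitivity
    spec = 1.0 - roc.one_minus_specificity
    if criterion == "balance":
        gap = np.abs(sens - spec)
        best = np.flatnonzero(gap == gap.min())
        pick = best[np.argmax(sens[best])]
    elif criterion == "youden":
        j = sens + spec - 1.0
        best = np.flatnonzero(j == j.max())
        pick = best[np.argmax(sens[best])]
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return float(roc.thresholds[pick])


def render_overlay(image, grid, labels_true, labels_pred, line_width: int = 2) -> np.ndarray:
    """Outcome overlay: red = true positive, green = false positive,
    blue = false negative patch outlines; true negatives are not drawn."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    out = image.copy()
    colors = {"tp": (1.0, 0.0, 0.0), "fp": (0.0, 1.0, 0.0), "fn": (0.0, 0.0, 1.0)}
    y = np.asarray(labels_true, dtype=int)
    p = np.asarray(labels_pred, dtype=int)
    for patch, yt, yp in zip(grid.patches, y, p):
        if yt == 1 and yp == 1:
            color = colors["tp"]
        elif yt == 0 and yp == 1:
            color = colors["fp"]
        elif yt == 1 and yp == 0:
            color = colors["fn"]
        else:
            continue
        top, left, h, w = patch.bounds
        lw = line_width
        out[top:top + lw, left:left + w] = color
        out[top + h - lw:top + h, left:left + w] = color
        out[top:top + h, left:left + lw] = color
        out[top:top + h, left + w - lw:left + w] = color
    return out


def count_overlay_rectangles(grid, labels_true, labels_pred) -> int:
    """Number of rectangles render_overlay would draw (TP + FP + FN)."""
    y = np.asarray(labels_true, dtype=int)
    p = np.asarray(labels_pred, dtype=int)
    return int(np.sum((y == 1) | (p == 1)))
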