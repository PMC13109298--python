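"""Evaluation metrics for segmentation, regression and binary classification.

Conventions follow the common remote-sensing usage: specificity, sensitivity,
accuracy and recall are reported as percentages in [0, 100]; IoU and Dice as
unitless fractions. Metrics whose denominator is empty are reported as NaN
("not available") rather than 0, so that aggregate statistics over many plots
are not silently deflated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "ClassCounts",
    "iou",
    "confusion_counts",
    "confusion_metrics",
    "regression_metrics",
    "classification_metrics",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel- or sample-level confusion counts for a binary problem."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise ValueError("confusion counts are all zero")


@dataclass(frozen=True)
class ClassCounts:
    """Per-class correct/incorrect counts for a binary classifier.

    ``t0``/``t1`` are correctly classified samples of class 0/1; ``f0``/``f1``
    are samples of class 0/1 misclassified as the other class.
    """

    t0: int
    t1: int
    f0: int
    f1: int

    @property
    def n(self) -> int:
        return self.t0 + self.t1 + self.f0 + self.f1


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union of two binary masks, in [0, 1].

    Raises ``ValueError`` when both masks are empty (the ratio is undefined).
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        raise ValueError("IoU undefined: both masks are empty")
    inter = np.count_nonzero(a & b)
    return inter / union


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel-wise confusion counts of a predicted mask against a truth mask."""
    p = np.asarray(pred, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if p.shape != t.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {t.shape}")
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


def confusion_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(specificity %, sensitivity %, Dice) from confusion counts.

    specificity = TN / (TN + FP) * 100
    sensitivity = TP / (TP + FN) * 100
    Dice        = 2 TP / (2 TP + FP + FN)

    A metric with zero denominator is NaN.
    """
    spec = c.tn / (c.tn + c.fp) * 100.0 if (c.tn + c.fp) > 0 else float("nan")
    sens = c.tp / (c.tp + c.fn) * 100.0 if (c.tp + c.fn) > 0 else float("nan")
    denom = 2 * c.tp + c.fp + c.fn
    dice = 2 * c.tp / denom if denom > 0 else float("nan")
    return spec, sens, dice


def regression_metrics(
    y: np.ndarray, y_hat: np.ndarray
) -> tuple[float, float, float, float]:
    """(R^2, RMSE, NRMSE %, MAPE %) of estimates against observations.

    NRMSE is the RMSE normalized by the observed range ``max(y) - min(y)``.
    R^2 is NaN when the observations are constant; NRMSE is NaN when the
    observed range is zero; MAPE is NaN when any observation is zero.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have equal length")
    if y.size < 2:
        raise ValueError("need at least two samples")
    resid = y - y_hat
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    y_range = float(y.max() - y.min())
    nrmse = rmse / y_range * 100.0 if y_range > 0 else float("nan")
    if np.any(y == 0):
        mape = float("nan")
    else:
        mape = float(np.mean(np.abs(resid / y))) * 100.0
    return r2, rmse, nrmse, mape


def classification_metrics(c: ClassCounts) -> tuple[float, float, float]:
    """(accuracy %, recall class 0 %, recall class 1 %).

    accuracy = (T0 + T1) / N * 100, recall_c = T_c / (T_c + F_c) * 100.
    The recall of a class absent from the evaluation set is NaN.
    """
    if c.n == 0:
        raise ValueError("no samples")
    acc = (c.t0 + c.t1) / c.n * 100.0
    r0 = c.t0 / (c.t0 + c.f0) * 100.0 if (c.t0 + c.f0) > 0 else float("nan")
    r1 = c.t1 / (c.t1 + c.f1) * 100.0 if (c.t1 + c.f1) > 0 else float("nan")
    return acc, r0, r1
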