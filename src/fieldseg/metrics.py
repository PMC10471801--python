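"""Confusion-matrix segmentation metrics: PA, per-class PA, mPA, IoU, mIoU.

With k object classes plus background, the (k+1) x (k+1) matrix entry
``counts[i, j]`` holds the number of pixels of true class i predicted as
class j.  Global pixel accuracy is trace/total; per-class PA is the
row-normalized diagonal (recall); IoU_i = p_ii / (row_i + col_i - p_ii).
Classes absent from both truth and prediction are excluded from the
unweighted means rather than scored 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionMatrix", "confusion_matrix", "pixel_accuracy",
           "mean_pixel_accuracy", "iou"]


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (c < 0).any():
            raise ValueError("confusion matrix entries must be >= 0")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def num_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


def confusion_matrix(pred_mask: np.ndarray, true_mask: np.ndarray,
                     k: int) -> ConfusionMatrix:
    """Tally a (k+1) x (k+1) matrix from a predicted and a true mask."""
    pred = np.asarray(pred_mask).ravel()
    true = np.asarray(true_mask).ravel()
    if pred.shape != true.shape:
        raise ValueError("masks must have the same shape")
    n = k + 1
    if pred.min(initial=0) < 0 or true.min(initial=0) < 0 or \
            pred.max(initial=0) >= n or true.max(initial=0) >= n:
        raise ValueError(f"labels must lie in [0, {k}]")
    counts = np.bincount(true.astype(np.int64) * n + pred.astype(np.int64),
                         minlength=n * n).reshape(n, n)
    return ConfusionMatrix(counts)


def pixel_accuracy(m: ConfusionMatrix) -> tuple[float, np.ndarray]:
    """(global PA, per-class PA vector; NaN marks classes with no truth)."""
    c = m.counts
    total = c.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    row = c.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(row > 0, np.diag(c) / row, np.nan)
    return float(np.trace(c) / total), per_class


def mean_pixel_accuracy(m: ConfusionMatrix) -> float:
    """Unweighted mean of the defined per-class PA values."""
    _, per_class = pixel_accuracy(m)
    defined = per_class[~np.isnan(per_class)]
    if defined.size == 0:
        raise ValueError("no class has any truth pixels")
    return float(defined.mean())


def iou(m: ConfusionMatrix) -> tuple[np.ndarray, float]:
    """(per-class IoU vector, mIoU); NaN marks classes with empty union."""
    c = m.counts
    if c.sum() == 0:
        raise ValueError("confusion matrix is empty")
    diag = np.diag(c).astype(np.float64)
    union = c.sum(axis=1) + c.sum(axis=0) - np.diag(c)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(union > 0, diag / union, np.nan)
    defined = per_class[~np.isnan(per_class)]
    if defined.size == 0:
        raise ValueError("every class has an empty union")
    return per_class, float(defined.mean())
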