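"""Segmentation evaluation metrics.

Four overlap ratios from the pixel confusion matrix —

* precision   = TP / (TP + FP)
* sensitivity = TP / (TP + FN)          (recall)
* IoU         = TP / (TP + FP + FN)     (Jaccard)
* Dice        = 2 TP / (2 TP + FP + FN) (= 2 IoU / (1 + IoU))

— and two surface distances between the contour point sets of prediction
and truth: ASD (symmetric mean nearest-neighbour distance) and HD95 (the
robust Hausdorff distance: max over the two directions of the 95th
percentile of directed nearest-neighbour distances).  Overlap ratios are
"bigger is better"; surface distances (pixel units) are "smaller is
better".  Ratios with a zero denominator are reported as NaN sentinels
rather than raising.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateMaskError, DimensionError
from .softlabel import extract_boundary

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "overlap_metrics",
    "surface_points",
    "asd",
    "hd95",
    "evaluate_masks",
]

logger = logging.getLogger(__name__)

# Reporting direction per metric: True = higher is better.
HIGHER_IS_BETTER = {
    "precision": True, "sensitivity": True, "iou": True, "dice": True,
    "asd": False, "hd95": False,
}


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixelwise confusion tallies between a predicted and true mask."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricReport:
    """The six evaluation metrics for one mask pair. Ratios in [0, 1],
    distances in pixels; NaN marks an undefined ratio."""

    precision: float = math.nan
    sensitivity: float = math.nan
    iou: float = math.nan
    dice: float = math.nan
    asd: float = math.nan
    hd95: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Tally TP/FP/FN/TN pixels between two binary masks."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise DimensionError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p = pred.astype(bool)
    t = truth.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("metric %s undefined (zero denominator)", name)
        return math.nan
    return num / den


def overlap_metrics(c: ConfusionCounts) -> MetricReport:
    """Compute the four confusion-based ratios from pixel tallies."""
    return MetricReport(
        precision=_ratio(c.tp, c.tp + c.fp, "precision"),
        sensitivity=_ratio(c.tp, c.tp + c.fn, "sensitivity"),
        iou=_ratio(c.tp, c.tp + c.fp + c.fn, "iou"),
        dice=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, "dice"),
    )


def surface_points(mask: np.ndarray) -> np.ndarray:
    """Contour coordinates of a binary mask (same 4-connectivity rule as
    the soft-label stage). Raises for constant masks."""
    pts = extract_boundary(mask).points
    if len(pts) == 0:
        raise DegenerateMaskError("mask has no surface (constant mask)")
    return np.asarray(pts, dtype=float)


def _directed_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Nearest-neighbour distance from every point of ``a`` to set ``b``."""
    d, _ = cKDTree(b).query(a, k=1)
    return np.atleast_1d(d)


def asd(a: np.ndarray, b: np.ndarray) -> float:
    """Average surface distance between two contour point sets:
    sum of both directed nearest-neighbour distance lists divided by the
    total number of surface points."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise DegenerateMaskError("empty surface set")
    d_ab = _directed_distances(a, b)
    d_ba = _directed_distances(b, a)
    return float((d_ab.sum() + d_ba.sum()) / (len(a) + len(b)))


def hd95(a: np.ndarray, b: np.ndarray) -> float:
    """95th-percentile Hausdorff distance between two contour point sets.

    The max over both directions of the 95th percentile (linear
    interpolation) of directed nearest-neighbour distances; discards the
    largest 5% in each direction so isolated outliers do not dominate.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise DegenerateMaskError("empty surface set")
    d_ab = _directed_distances(a, b)
    d_ba = _directed_distances(b, a)
    return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))


def evaluate_masks(pred: np.ndarray, truth: np.ndarray) -> MetricReport:
    """All six metrics for one predicted/true mask pair.

    Surface distances are NaN when either mask is constant (no contour).
    """
    report = overlap_metrics(confusion_counts(pred, truth))
    try:
        sa = surface_points(pred)
        sb = surface_points(truth)
    except DegenerateMaskError:
        logger.warning("surface metrics undefined for a constant mask")
        return report
    report.asd = asd(sa, sb)
    report.hd95 = hd95(sa, sb)
    return report
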