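"""Detection and segmentation evaluation: IoU, COCO-style AP, Dice.

Boxes are continuous half-open regions ``[x_min, x_max) x [y_min, y_max)``
so areas are exact and integer-aligned boxes rasterise without off-by-one
ambiguity.  AP follows the MS-COCO convention (ranked detections, greedy
single-use matching, 101-point interpolated precision), with one deliberate
deviation: a detection counts as correct only when its IoU is *strictly
greater* than the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

COCO_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclass(frozen=True)
class BBox:
    """Axis-aligned half-open box [x_min, x_max) x [y_min, y_max)."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(f"box must have positive area: {self}")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)


@dataclass(frozen=True)
class Detection:
    """A detector output: a box with confidence, attached to one slice."""

    box: BBox
    confidence: float
    theta_deg: float = 0.0
    slice_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must lie in [0, 1], got {self.confidence}")


@dataclass
class MaskImage:
    """Boolean pixel mask aligned with a slice image; shape (width, height)."""

    pixels: np.ndarray
    theta_deg: float = 0.0
    slice_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask pixels must be 2D")

    @property
    def count(self) -> int:
        return int(self.pixels.sum())


@dataclass
class PRCurve:
    """Cumulative precision/recall along a confidence-ranked detection list."""

    precision: np.ndarray
    recall: np.ndarray

    def __post_init__(self) -> None:
        self.precision = np.asarray(self.precision, dtype=float)
        self.recall = np.asarray(self.recall, dtype=float)
        if np.any(np.diff(self.recall) < 0):
            raise ValueError("recall must be non-decreasing")
        if np.any((self.precision < 0) | (self.precision > 1)):
            raise ValueError("precision entries must lie in [0, 1]")


def _box_iou(a: BBox, b: BBox) -> float:
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def iou(a, b) -> float:
    """Intersection over union of two boxes or two same-shape masks."""
    if isinstance(a, BBox) and isinstance(b, BBox):
        return _box_iou(a, b)
    pa = a.pixels if isinstance(a, MaskImage) else np.asarray(a, dtype=bool)
    pb = b.pixels if isinstance(b, MaskImage) else np.asarray(b, dtype=bool)
    if pa.shape != pb.shape:
        raise ValueError("mask shapes differ")
    union = np.logical_or(pa, pb).sum()
    if union == 0:
        raise ValueError("both regions are empty")
    return float(np.logical_and(pa, pb).sum() / union)


def _rank(dets: Sequence[Detection]) -> list[int]:
    """Indices sorting by descending confidence, stable for ties."""
    return sorted(range(len(dets)), key=lambda i: -dets[i].confidence)


def match_detections(
    dets: Sequence[Detection], gts: Sequence[BBox], iou_thresh: float
) -> list[bool]:
    """Greedy TP/FP labelling in confidence rank order.

    Each ground truth may be matched at most once; a detection is a true
    positive iff its best IoU against a still-unmatched ground truth is
    strictly greater than ``iou_thresh``.  Returns labels in rank order.
    """
    labels: list[bool] = []
    unmatched = list(range(len(gts)))
    for i in _rank(dets):
        best_j, best_iou = -1, 0.0
        for j in unmatched:
            v = _box_iou(dets[i].box, gts[j])
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou > iou_thresh:
            labels.append(True)
            unmatched.remove(best_j)
        else:
            labels.append(False)
    return labels


def pr_curve(labels: Sequence[bool], n_gt: int) -> PRCurve:
    """Cumulative precision/recall for a ranked TP/FP sequence."""
    if n_gt < 1:
        raise ValueError("n_gt must be >= 1")
    tp = np.cumsum(np.asarray(labels, dtype=bool))
    k = np.arange(1, len(labels) + 1)
    return PRCurve(precision=tp / k, recall=tp / n_gt)


def average_precision(labels: Sequence[bool], n_gt: int) -> float:
    """101-point interpolated AP of a ranked TP/FP sequence.

    Precision is interpolated as the maximum precision achieved at any
    recall >= r, then averaged over r in {0.00, 0.01, ..., 1.00}.
    """
    if n_gt < 1:
        raise ValueError("n_gt must be >= 1")
    if len(labels) == 0:
        return 0.0
    curve = pr_curve(labels, n_gt)
    # envelope[i] = max precision at rank >= i
    envelope = np.maximum.accumulate(curve.precision[::-1])[::-1]
    recall_points = np.linspace(0.0, 1.0, 101)
    idx = np.searchsorted(curve.recall, recall_points - 1e-12, side="left")
    interp = np.where(idx < len(envelope), envelope[np.minimum(idx, len(envelope) - 1)], 0.0)
    return float(interp.mean())


def _pooled_labels(
    dets: Sequence[Detection], gts_by_slice: Mapping[str, Sequence[BBox]], thresh: float
) -> list[bool]:
    """Rank detections across all slices jointly, match within each slice."""
    unmatched = {sid: list(range(len(g))) for sid, g in gts_by_slice.items()}
    labels = []
    for i in _rank(dets):
        det = dets[i]
        pool = unmatched.get(det.slice_id, [])
        best_j, best_iou = -1, 0.0
        for j in pool:
            v = _box_iou(det.box, gts_by_slice[det.slice_id][j])
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou > thresh:
            labels.append(True)
            pool.remove(best_j)
        else:
            labels.append(False)
    return labels


def ap_suite(dets: Sequence[Detection], gts) -> dict[str, float]:
    """AP50, AP75 and AP(0.5:0.95) for a detection set.

    ``gts`` is either a sequence of boxes (single image) or a mapping
    ``slice_id -> boxes``; detections are ranked jointly across slices and
    matched within their own slice.
    """
    if isinstance(gts, Mapping):
        gts_by_slice = {sid: list(g) for sid, g in gts.items()}
    else:
        sids = {d.slice_id for d in dets} or {""}
        if len(sids) > 1:
            raise ValueError("detections span multiple slices; pass gts as a mapping")
        gts_by_slice = {next(iter(sids)): list(gts)}
    n_gt = sum(len(g) for g in gts_by_slice.values())
    aps = {
        t: average_precision(_pooled_labels(dets, gts_by_slice, t), n_gt)
        for t in COCO_THRESHOLDS
    }
    return {
        "AP50": aps[0.5],
        "AP75": aps[0.75],
        "AP(0.5:0.95)": float(np.mean([aps[t] for t in COCO_THRESHOLDS])),
    }


def dice(p, g) -> float:
    """Dice coefficient 2|P n G| / (|P| + |G|) of two same-shape masks."""
    pa = p.pixels if isinstance(p, MaskImage) else np.asarray(p, dtype=bool)
    pb = g.pixels if isinstance(g, MaskImage) else np.asarray(g, dtype=bool)
    if pa.shape != pb.shape:
        raise ValueError("mask shapes differ")
    total = pa.sum() + pb.sum()
    if total == 0:
        raise ValueError("both masks are empty")
    return float(2.0 * np.logical_and(pa, pb).sum() / total)
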