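"""Evaluation of instance segmentations against ground truth.

Implements the metric suite used to benchmark automatic particle
segmentation: IoU-based one-to-one instance matching, particle
detection rate, false detections per 100 detections, mean average
precision over the IoU threshold grid 0.50:0.05:0.95 (COCO convention;
a median reduction is available as an option), Bland-Altman agreement
between paired size estimates, and the count of touching/overlapping
particle pairs after 1-pixel mask dilation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .imaging_io import InstanceSet

__all__ = [
    "MatchResult",
    "EvalReport",
    "BlandAltman",
    "iou_matrix",
    "match_instances",
    "detection_stats",
    "mean_ap",
    "bland_altman",
    "overlapping_pairs",
    "evaluate",
]

IOU_GRID = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))


@dataclass
class MatchResult:
    """One-to-one matching between predictions and truths.

    ``pairs`` holds (prediction index, truth index, IoU) for each match;
    all paired IoUs are >= the threshold used.
    """

    pairs: list[tuple[int, int, float]]
    unmatched_pred: list[int]
    unmatched_truth: list[int]
    n_pred: int
    n_truth: int


@dataclass
class EvalReport:
    detection_rate: float  # percent of truths detected
    false_per_100: float  # false positives per 100 detections
    mAP: float
    n_truth: int
    n_pred: int
    overlapping_pairs_pred: Optional[int] = None
    overlapping_pairs_truth: Optional[int] = None


@dataclass
class BlandAltman:
    """Agreement between two paired size estimates (differences a - b)."""

    bias: float
    lower_limit: float
    upper_limit: float
    points: list[tuple[float, float]]  # (pairwise mean, difference)


def _pair_iou(a: InstanceSet, i: int, b: InstanceSet, j: int) -> float:
    ar0, ac0, ar1, ac1 = a.bbox(i)
    br0, bc0, br1, bc1 = b.bbox(j)
    r0, r1 = max(ar0, br0), min(ar1, br1)
    c0, c1 = max(ac0, bc0), min(ac1, bc1)
    if r0 > r1 or c0 > c1:
        return 0.0
    ca = a.crop(i)[r0 - ar0 : r1 - ar0 + 1, c0 - ac0 : c1 - ac0 + 1]
    cb = b.crop(j)[r0 - br0 : r1 - br0 + 1, c0 - bc0 : c1 - bc0 + 1]
    inter = int(np.logical_and(ca, cb).sum())
    if inter == 0:
        return 0.0
    union = a.area(i) + b.area(j) - inter
    return inter / union


def iou_matrix(pred: InstanceSet, truth: InstanceSet) -> np.ndarray:
    """Dense IoU matrix, shape (n_pred, n_truth)."""
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth masks must be congruent")
    out = np.zeros((len(pred), len(truth)))
    for i in range(len(pred)):
        for j in range(len(truth)):
            out[i, j] = _pair_iou(pred, i, truth, j)
    return out


def match_instances(
    pred: InstanceSet, truth: InstanceSet, iou_threshold: float = 0.5
) -> MatchResult:
    """Greedy one-to-one matching in descending IoU order.

    Ties are broken by higher prediction score, then by lower prediction
    index; candidate pairs below ``iou_threshold`` are rejected.
    """
    iou = iou_matrix(pred, truth)
    cand = []
    for i in range(len(pred)):
        score = pred.scores[i] if pred.scores is not None else 0.0
        for j in range(len(truth)):
            if iou[i, j] >= iou_threshold:
                cand.append((-iou[i, j], -score, i, j))
    cand.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    pairs = []
    for neg_iou, _, i, j in cand:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        pairs.append((i, j, -neg_iou))
    return MatchResult(
        pairs=pairs,
        unmatched_pred=[i for i in range(len(pred)) if i not in used_p],
        unmatched_truth=[j for j in range(len(truth)) if j not in used_t],
        n_pred=len(pred),
        n_truth=len(truth),
    )


def detection_stats(match: MatchResult) -> tuple[float, float]:
    """(detection rate %, false positives per 100 detections).

    Undefined statistics (no truths / no predictions) are NaN.
    """
    n_matched = len(match.pairs)
    rate = 100.0 * n_matched / match.n_truth if match.n_truth else float("nan")
    false = (
        100.0 * len(match.unmatched_pred) / match.n_pred if match.n_pred else float("nan")
    )
    return rate, false


def _ap_at(iou: np.ndarray, order: np.ndarray, n_truth: int, thr: float) -> float:
    """AP at one IoU threshold: greedy score-ordered matching, PR envelope."""
    matched_t: set[int] = set()
    tp = np.zeros(order.size)
    for rank, i in enumerate(order):
        best_j, best_iou = -1, thr
        for j in range(n_truth):
            if j in matched_t:
                continue
            if iou[i, j] >= best_iou:
                best_iou, best_j = iou[i, j], j
        if best_j >= 0:
            matched_t.add(best_j)
            tp[rank] = 1.0
    tp_cum = np.cumsum(tp)
    recall = tp_cum / n_truth
    precision = tp_cum / np.arange(1, order.size + 1)
    # all-point interpolation: precision envelope
    env = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    prev_r = 0.0
    for r, p in zip(recall, env):
        if r > prev_r:
            ap += (r - prev_r) * p
            prev_r = r
    return float(ap)


def mean_ap(
    pred: InstanceSet,
    truth: InstanceSet,
    iou_thresholds: Sequence[float] = IOU_GRID,
    reduce: str = "mean",
) -> float:
    """AP averaged over the IoU grid 0.50:0.05:0.95.

    Predictions are swept in descending score order (ties by index); at
    each threshold the precision-recall curve uses greedy matching and
    the all-point (envelope) interpolation.  ``reduce="median"`` takes
    the median of the per-threshold APs instead of the mean.
    """
    if len(truth) == 0:
        return float("nan")
    if len(pred) == 0:
        return 0.0
    if pred.scores is None:
        raise ValueError("mean_ap requires prediction scores")
    iou = iou_matrix(pred, truth)
    order = np.argsort(-np.asarray(pred.scores), kind="stable")
    aps = [_ap_at(iou, order, len(truth), t) for t in iou_thresholds]
    if reduce == "mean":
        return float(np.mean(aps))
    if reduce == "median":
        return float(np.median(aps))
    raise ValueError("reduce must be 'mean' or 'median'")


def bland_altman(sizes_a: Sequence[float], sizes_b: Sequence[float]) -> BlandAltman:
    """Bland-Altman agreement: bias and bias +/- 1.96 * SD of differences."""
    a = np.asarray(list(sizes_a), dtype=float)
    b = np.asarray(list(sizes_b), dtype=float)
    if a.size != b.size:
        raise ValueError("paired size lists must have equal length")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltman(
        bias=bias,
        lower_limit=bias - 1.96 * sd,
        upper_limit=bias + 1.96 * sd,
        points=list(zip(((a + b) / 2.0).tolist(), diff.tolist())),
    )


def overlapping_pairs(instances: InstanceSet, dilate_px: int = 1) -> int:
    """Unordered pairs of masks that intersect after each is dilated.

    Dilation uses the 8-connected (3 x 3 square) structuring element
    applied ``dilate_px`` times; the count is monotone nondecreasing in
    ``dilate_px``.
    """
    n = len(instances)
    structure = np.ones((3, 3), dtype=bool)
    crops = []
    boxes = []
    for i in range(n):
        r0, c0, r1, c1 = instances.bbox(i)
        if dilate_px > 0:
            crop = np.pad(instances.crop(i), dilate_px)
            crop = ndimage.binary_dilation(crop, structure=structure, iterations=dilate_px)
            boxes.append((r0 - dilate_px, c0 - dilate_px, r1 + dilate_px, c1 + dilate_px))
        else:
            crop = instances.crop(i)
            boxes.append((r0, c0, r1, c1))
        crops.append(crop)
    count = 0
    for i in range(n):
        ar0, ac0, ar1, ac1 = boxes[i]
        for j in range(i + 1, n):
            br0, bc0, br1, bc1 = boxes[j]
            r0, r1 = max(ar0, br0), min(ar1, br1)
            c0, c1 = max(ac0, bc0), min(ac1, bc1)
            if r0 > r1 or c0 > c1:
                continue
            ca = crops[i][r0 - ar0 : r1 - ar0 + 1, c0 - ac0 : c1 - ac0 + 1]
            cb = crops[j][r0 - br0 : r1 - br0 + 1, c0 - bc0 : c1 - bc0 + 1]
            if np.logical_and(ca, cb).any():
                count += 1
    return count


def evaluate(
    pred: InstanceSet,
    truth: InstanceSet,
    iou_threshold: float = 0.5,
    *,
    dilate_px: int = 1,
    reduce: str = "mean",
) -> EvalReport:
    """Full report: detection rate, false per 100, mAP and overlap counts."""
    match = match_instances(pred, truth, iou_threshold)
    rate, false = detection_stats(match)
    m = mean_ap(pred, truth, reduce=reduce) if pred.scores is not None else float("nan")
    return EvalReport(
        detection_rate=rate,
        false_per_100=false,
        mAP=m,
        n_truth=len(truth),
        n_pred=len(pred),
        overlapping_pairs_pred=overlapping_pairs(pred, dilate_px),
        overlapping_pairs_truth=overlapping_pairs(truth, dilate_px),
    )
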