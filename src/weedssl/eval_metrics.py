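"""Detection evaluation: IoU, greedy matching, AP and mAP@[0.5:0.95].

AP summarizes the precision-recall curve of one class at one IoU
threshold; we realize the P(R) integral as the COCO 101-point
interpolation (mean over recall grid {0, 0.01, ..., 1} of the maximum
precision achieved at recall >= r).  mAP is the unweighted class mean and
mAP@[0.5:0.95] additionally averages over IoU thresholds
{0.50, 0.55, ..., 0.95}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .boxes import BoundingBox, boxes_to_array, box_classes, iou_matrix

logger = logging.getLogger(__name__)

#: COCO-style IoU threshold ladder.
IOU_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2).tolist())

#: Recall grid for interpolated AP.
RECALL_GRID = np.linspace(0.0, 1.0, 101)

#: Detections kept per image before evaluation (descending score).
MAX_DETECTIONS_PER_IMAGE = 100


class EvaluationError(ValueError):
    """No evaluable classes or invalid evaluation inputs."""


def iou(a, b) -> float:
    """Intersection-over-union of two boxes (corner form or BoundingBox)."""
    a = a.as_array() if isinstance(a, BoundingBox) else np.asarray(a, float)
    b = b.as_array() if isinstance(b, BoundingBox) else np.asarray(b, float)
    if a[2] <= a[0] or a[3] <= a[1] or b[2] <= b[0] or b[3] <= b[1]:
        raise ValueError("degenerate box in IoU")
    return float(iou_matrix(a[None, :], b[None, :])[0, 0])


@dataclass
class MatchResult:
    """Greedy match of one image's detections against its ground truth.

    Detections are stored in evaluation order (descending score, ties by
    original index); ``tp[i]`` says whether detection ``i`` matched a
    previously unmatched ground-truth box of its class at ``iou_threshold``.
    """

    scores: np.ndarray  # (n_det,) float, evaluation order
    det_classes: np.ndarray  # (n_det,) int
    tp: np.ndarray  # (n_det,) bool
    matched_gt: np.ndarray  # (n_det,) int, -1 if FP
    n_gt_per_class: dict[int, int]
    iou_threshold: float


def _det_arrays(detections) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract (boxes, scores, classes) from Detection-like objects."""
    if len(detections) == 0:
        return (
            np.zeros((0, 4)), np.zeros(0), np.zeros(0, dtype=np.int64),
        )
    boxes = np.stack([d.box.as_array() for d in detections])
    scores = np.array([d.score for d in detections], dtype=np.float64)
    classes = np.array([d.class_id for d in detections], dtype=np.int64)
    return boxes, scores, classes


def match_detections(
    detections, ground_truth: list[BoundingBox], iou_threshold: float
) -> MatchResult:
    """Class-wise greedy matching in descending score order.

    Each detection matches the highest-IoU still-unmatched ground-truth box
    of its own class provided IoU >= ``iou_threshold``; otherwise it is a
    false positive.  Ties in score break by original detection index, ties
    in IoU by lower ground-truth index.
    """
    det_boxes, scores, det_cls = _det_arrays(detections)
    if len(scores) > MAX_DETECTIONS_PER_IMAGE:
        keep = np.lexsort((np.arange(len(scores)), -scores))[
            :MAX_DETECTIONS_PER_IMAGE
        ]
        keep.sort()
        det_boxes, scores, det_cls = det_boxes[keep], scores[keep], det_cls[keep]
    gt_boxes = boxes_to_array(ground_truth)
    gt_cls = box_classes(ground_truth)

    order = np.lexsort((np.arange(len(scores)), -scores))
    tp = np.zeros(len(order), dtype=bool)
    matched = np.full(len(order), -1, dtype=np.int64)
    gt_taken = np.zeros(len(gt_cls), dtype=bool)
    ious = iou_matrix(det_boxes, gt_boxes) if len(gt_cls) else None
    for rank, di in enumerate(order):
        same = np.nonzero((gt_cls == det_cls[di]) & ~gt_taken)[0]
        if same.size == 0:
            continue
        cand = ious[di, same]
        best = int(same[np.argmax(cand)])
        if ious[di, best] >= iou_threshold:
            tp[rank] = True
            matched[rank] = best
            gt_taken[best] = True
    n_gt = {int(c): int(np.sum(gt_cls == c)) for c in np.unique(gt_cls)}
    return MatchResult(
        scores=scores[order],
        det_classes=det_cls[order],
        tp=tp,
        matched_gt=matched,
        n_gt_per_class=n_gt,
        iou_threshold=float(iou_threshold),
    )


@dataclass
class PRCurve:
    """Interpolated precision at the fixed recall grid."""

    recall_grid: np.ndarray
    precision: np.ndarray

    def __post_init__(self) -> None:
        p = self.precision
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("precision outside [0, 1]")
        if np.any(np.diff(p) > 1e-12):
            raise ValueError("interpolated precision must be non-increasing")


def pr_curve(scores: np.ndarray, tp: np.ndarray, n_positive: int) -> PRCurve:
    """Interpolated PR curve from pooled, score-sorted TP flags."""
    order = np.lexsort((np.arange(len(scores)), -np.asarray(scores)))
    tp_sorted = np.asarray(tp, dtype=np.float64)[order]
    tp_cum = np.cumsum(tp_sorted)
    fp_cum = np.cumsum(1.0 - tp_sorted)
    recall = tp_cum / n_positive
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1e-12)
    # running max from the right = max precision at recall >= r
    p_interp = np.maximum.accumulate(precision[::-1])[::-1]
    out = np.zeros_like(RECALL_GRID)
    # tolerance so a recall exactly on a grid point is not lost to float error
    idx = np.searchsorted(recall, RECALL_GRID - 1e-10, side="left")
    valid = idx < len(recall)
    out[valid] = p_interp[idx[valid]]
    return PRCurve(RECALL_GRID.copy(), out)


def average_precision_from_flags(
    scores: np.ndarray, tp: np.ndarray, n_positive: int
) -> float:
    """101-point interpolated AP for one class at one IoU threshold."""
    if n_positive < 1:
        raise EvaluationError("AP undefined with zero ground-truth instances")
    if len(scores) == 0:
        return 0.0
    return float(pr_curve(np.asarray(scores), np.asarray(tp), n_positive).precision.mean())


def average_precision(match: MatchResult, class_id: int | None = None) -> float:
    """AP of one class from a single match result.

    With ``class_id`` omitted the match must involve exactly one class.
    """
    if class_id is None:
        evaluable = list(match.n_gt_per_class)
        if len(evaluable) != 1:
            raise EvaluationError(
                "class_id required when several classes have ground truth"
            )
        class_id = evaluable[0]
    npos = match.n_gt_per_class.get(class_id, 0)
    sel = match.det_classes == class_id
    return average_precision_from_flags(match.scores[sel], match.tp[sel], npos)


@dataclass
class APReport:
    """Per-class x per-threshold AP and its aggregations.

    ``ap[c][t]`` is NaN when class ``c`` has no ground truth in the test
    set; such classes are excluded from every mean (and logged).
    """

    class_ids: tuple[int, ...]
    thresholds: tuple[float, ...]
    ap: np.ndarray  # (n_classes, n_thresholds), NaN = not evaluable
    excluded_classes: tuple[int, ...] = field(default=())

    def per_class_mean(self) -> dict[int, float]:
        """Mean AP across thresholds, per evaluable class."""
        return {
            c: float(np.mean(self.ap[i]))
            for i, c in enumerate(self.class_ids)
            if not np.any(np.isnan(self.ap[i]))
        }

    def map_at(self, threshold: float) -> float:
        """Class-mean AP at one IoU threshold."""
        t = int(np.argmin(np.abs(np.asarray(self.thresholds) - threshold)))
        if abs(self.thresholds[t] - threshold) > 1e-9:
            raise EvaluationError(f"threshold {threshold} not evaluated")
        col = self.ap[:, t]
        col = col[~np.isnan(col)]
        if col.size == 0:
            raise EvaluationError("no evaluable classes")
        return float(col.mean())

    @property
    def map_50_95(self) -> float:
        """mAP@[0.5:0.95]: class mean, then threshold mean."""
        rows = self.ap[~np.isnan(self.ap).any(axis=1)]
        if rows.size == 0:
            raise EvaluationError("no evaluable classes")
        return float(rows.mean(axis=0).mean())

    def to_dict(self) -> dict:
        return {
            "thresholds": list(self.thresholds),
            "per_class_ap": {
                str(c): [None if np.isnan(v) else float(v) for v in self.ap[i]]
                for i, c in enumerate(self.class_ids)
            },
            "per_class_map_50_95": {
                str(c): v for c, v in self.per_class_mean().items()
            },
            "map_50": self.map_at(0.50),
            "map_50_95": self.map_50_95,
            "excluded_classes": list(self.excluded_classes),
        }


def evaluate_detections(
    detections_by_image: dict[int, list],
    ground_truth_by_image: dict[int, list[BoundingBox]],
    num_classes: int,
    thresholds: tuple[float, ...] = IOU_THRESHOLDS,
) -> APReport:
    """Dataset-level AP report over an IoU threshold ladder.

    Detections and ground truth are keyed by image id; images with no entry
    on either side contribute empty lists.
    """
    image_ids = sorted(set(detections_by_image) | set(ground_truth_by_image))
    n_gt = np.zeros(num_classes, dtype=np.int64)
    for img in image_ids:
        for b in ground_truth_by_image.get(img, []):
            if b.class_id >= num_classes:
                raise EvaluationError(
                    f"ground-truth class {b.class_id} outside category table"
                )
            n_gt[b.class_id] += 1
    evaluable = np.nonzero(n_gt > 0)[0]
    excluded = tuple(int(c) for c in np.nonzero(n_gt == 0)[0])
    if evaluable.size == 0:
        raise EvaluationError("no class has ground-truth instances")
    if excluded:
        logger.info("classes with no ground truth excluded from mAP: %s", excluded)

    ap = np.full((num_classes, len(thresholds)), np.nan)
    for t_idx, thr in enumerate(thresholds):
        pooled_scores: dict[int, list] = {int(c): [] for c in evaluable}
        pooled_tp: dict[int, list] = {int(c): [] for c in evaluable}
        for img in image_ids:
            match = match_detections(
                detections_by_image.get(img, []),
                ground_truth_by_image.get(img, []),
                thr,
            )
            for c in evaluable:
                sel = match.det_classes == c
                pooled_scores[int(c)].extend(match.scores[sel].tolist())
                pooled_tp[int(c)].extend(match.tp[sel].tolist())
        for c in evaluable:
            ap[c, t_idx] = average_precision_from_flags(
                np.asarray(pooled_scores[int(c)]),
                np.asarray(pooled_tp[int(c)]),
                int(n_gt[c]),
            )
    return APReport(
        class_ids=tuple(range(num_classes)),
        thresholds=tuple(float(t) for t in thresholds),
        ap=ap,
        excluded_classes=excluded,
    )


def mean_average_precision(per_class_ap: dict[int, float]) -> float:
    """Unweighted class mean of per-class AP values."""
    if not per_class_ap:
        raise EvaluationError("no evaluable classes")
    return float(np.mean(list(per_class_ap.values())))


def relative_performance(semi_map: float, sup_full_map: float) -> float:
    """Semi-supervised mAP as a percentage of the fully-supervised mAP.

    Returns ``100 * semi / sup`` rounded to two decimals, e.g. a
    semi-supervised 49.20 against a supervised 56.75 gives 86.70.
    """
    if sup_full_map <= 0:
        raise ValueError("supervised reference mAP must be positive")
    return round(100.0 * semi_map / sup_full_map, 2)
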