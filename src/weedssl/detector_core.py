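"""Miniature single-level dense detector in anchor-free and anchor-based
variants.

The anchor-free variant follows the FCOS recipe at desk scale: every
feature-grid location predicts per-class sigmoid scores, a centerness
score, four nonnegative distances (left, top, right, bottom) to the sides
of its box, and four Laplace scale parameters quantifying localization
uncertainty.  The anchor-based variant is a minimal single-stage head (3
scales x 3 aspect ratios per location, IoU 0.5/0.4 assignment) standing in
for a two-stage detector at this scale.

The learnable part is a per-location MLP over a fixed multi-scale pooled
color/contrast feature stem; gradients for the focal, GIoU, centerness and
Laplace negative-log-likelihood losses are computed analytically (see
:mod:`weedssl._nn`).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._nn import MLPWithHeads, sigmoid, softplus
from .boxes import BoundingBox, boxes_to_array, box_classes, iou_matrix

_STEM_OFFSETS = 2  # neighborhood half-width (5x5 window)
_STEM_DILATIONS = (1, 3)
_STEM_STATS = 6  # per-cell mean + std over RGB
FEATURE_DIM = _STEM_STATS * (2 * _STEM_OFFSETS + 1) ** 2 * len(_STEM_DILATIONS)

_FOCAL_PRIOR = 0.01  # initial foreground probability for the cls head
_UNC_CLIP = 6.0  # log-scale clamp for the uncertainty branch


class ShapeError(ValueError):
    """Image size incompatible with the detector stride."""


# ---------------------------------------------------------------------------
# Grid, targets, geometry


@dataclass(frozen=True)
class FeatureGrid:
    """Single-level feature grid; cell (i, j) sits at image point
    ``((j + 0.5) * stride, (i + 0.5) * stride)``."""

    stride: int
    n_rows: int
    n_cols: int
    image_width: int
    image_height: int

    @classmethod
    def for_image(cls, height: int, width: int, stride: int) -> "FeatureGrid":
        if height % stride or width % stride:
            raise ShapeError(
                f"image size {width}x{height} not divisible by stride {stride}"
            )
        return cls(stride, height // stride, width // stride, width, height)

    @property
    def n_locations(self) -> int:
        return self.n_rows * self.n_cols

    def centers(self) -> np.ndarray:
        """(N, 2) array of (x, y) image points, row-major."""
        ys = (np.arange(self.n_rows) + 0.5) * self.stride
        xs = (np.arange(self.n_cols) + 0.5) * self.stride
        xx, yy = np.meshgrid(xs, ys)
        return np.stack([xx.ravel(), yy.ravel()], axis=1)


@dataclass
class DenseTargets:
    """Per-location training targets for the anchor-free head.

    ``labels[i] == -1`` marks background; positive locations carry
    regression distances (l, t, r, b), a centerness target and the index of
    their assigned box.
    """

    labels: np.ndarray  # (N,) int, -1 = background
    reg: np.ndarray  # (N, 4) distances, zeros at background
    centerness: np.ndarray  # (N,), zeros at background
    assigned: np.ndarray  # (N,) box index, -1 at background

    @property
    def positive_mask(self) -> np.ndarray:
        return self.labels >= 0


@dataclass
class AnchorTargets:
    """Per-anchor assignment for the anchor-based head.

    ``status``: 1 positive, 0 negative, -1 ignored.
    """

    status: np.ndarray  # (Na,) int
    labels: np.ndarray  # (Na,) class id at positives, -1 elsewhere
    assigned: np.ndarray  # (Na,) gt index, -1 elsewhere
    gt_boxes: np.ndarray  # (M, 4) corner form

    @property
    def positive_mask(self) -> np.ndarray:
        return self.status == 1


def centerness_target(l: float, t: float, r: float, b: float) -> float:
    """FCOS-style centerness: sqrt(min(l,r)/max(l,r) * min(t,b)/max(t,b)).

    Equals 1 iff the location is the box center along both axes.
    """
    if min(l, t, r, b) <= 0:
        raise ValueError("centerness requires strictly positive distances")
    return float(
        np.sqrt((min(l, r) / max(l, r)) * (min(t, b) / max(t, b)))
    )


def _centerness_vec(ltrb: np.ndarray) -> np.ndarray:
    l, t, r, b = ltrb[:, 0], ltrb[:, 1], ltrb[:, 2], ltrb[:, 3]
    lr = np.minimum(l, r) / np.maximum(l, r)
    tb = np.minimum(t, b) / np.maximum(t, b)
    return np.sqrt(lr * tb)


def assign_targets_anchor_free(
    boxes: list[BoundingBox], grid: FeatureGrid
) -> DenseTargets:
    """All-inside-box assignment without center sampling.

    Every location strictly inside at least one box is foreground and is
    assigned to the smallest-area such box (ties to the lowest box index);
    everything else is background.
    """
    n = grid.n_locations
    labels = np.full(n, -1, dtype=np.int64)
    reg = np.zeros((n, 4))
    ctr = np.zeros(n)
    assigned = np.full(n, -1, dtype=np.int64)
    if not boxes:
        return DenseTargets(labels, reg, ctr, assigned)
    arr = boxes_to_array(boxes)
    cls = box_classes(boxes)
    centers = grid.centers()
    l = centers[:, 0:1] - arr[None, :, 0]
    t = centers[:, 1:2] - arr[None, :, 1]
    r = arr[None, :, 2] - centers[:, 0:1]
    b = arr[None, :, 3] - centers[:, 1:2]
    inside = (
        (l > 0) & (t > 0) & (r > 0) & (b > 0)
    )  # strict: on-the-edge locations are background
    areas = (arr[:, 2] - arr[:, 0]) * (arr[:, 3] - arr[:, 1])
    masked = np.where(inside, areas[None, :], np.inf)
    best = np.argmin(masked, axis=1)  # first minimum -> lowest index on ties
    pos = inside[np.arange(n), best]
    labels[pos] = cls[best[pos]]
    assigned[pos] = best[pos]
    idx = np.nonzero(pos)[0]
    reg[idx, 0] = l[idx, best[idx]]
    reg[idx, 1] = t[idx, best[idx]]
    reg[idx, 2] = r[idx, best[idx]]
    reg[idx, 3] = b[idx, best[idx]]
    ctr[idx] = _centerness_vec(reg[idx])
    return DenseTargets(labels, reg, ctr, assigned)


def generate_anchors(
    grid: FeatureGrid,
    sizes: tuple[float, ...],
    aspects: tuple[float, ...],
) -> np.ndarray:
    """(N * A, 4) corner-form anchors centered on grid cells.

    ``aspects`` are width/height ratios; anchor area is ``size**2``.
    """
    centers = grid.centers()
    shapes = []
    for s in sizes:
        for a in aspects:
            w = s * np.sqrt(a)
            h = s / np.sqrt(a)
            shapes.append((w, h))
    shapes = np.asarray(shapes)  # (A, 2)
    cx = centers[:, None, 0]
    cy = centers[:, None, 1]
    w = shapes[None, :, 0] / 2.0
    h = shapes[None, :, 1] / 2.0
    out = np.stack([cx - w, cy - h, cx + w, cy + h], axis=2)
    return out.reshape(-1, 4)


def assign_targets_anchor_based(
    boxes: list[BoundingBox],
    anchors: np.ndarray,
    pos_iou: float = 0.5,
    neg_iou: float = 0.4,
) -> AnchorTargets:
    """IoU-band anchor assignment (positive >= 0.5, negative < 0.4,
    ignored in between); each ground-truth box also claims its best-IoU
    anchor."""
    na = len(anchors)
    status = np.zeros(na, dtype=np.int64)
    labels = np.full(na, -1, dtype=np.int64)
    assigned = np.full(na, -1, dtype=np.int64)
    gt = boxes_to_array(boxes)
    if not boxes:
        return AnchorTargets(status, labels, assigned, gt)
    cls = box_classes(boxes)
    ious = iou_matrix(anchors, gt)
    best = np.argmax(ious, axis=1)
    best_iou = ious[np.arange(na), best]
    status[best_iou >= pos_iou] = 1
    status[(best_iou >= neg_iou) & (best_iou < pos_iou)] = -1
    pos = status == 1
    assigned[pos] = best[pos]
    # every gt claims its best anchor (ties -> lowest anchor index)
    claim = np.argmax(ious, axis=0)
    status[claim] = 1
    assigned[claim] = np.arange(len(boxes))
    labels[status == 1] = cls[assigned[status == 1]]
    return AnchorTargets(status, labels, assigned, gt)


def decode_boxes(grid: FeatureGrid, distances: np.ndarray) -> np.ndarray:
    """Corner boxes from per-location (l, t, r, b) distances, clipped to
    image bounds."""
    d = np.asarray(distances, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("regression distances must be nonnegative")
    c = grid.centers()
    out = np.stack(
        [
            c[:, 0] - d[:, 0],
            c[:, 1] - d[:, 1],
            c[:, 0] + d[:, 2],
            c[:, 1] + d[:, 3],
        ],
        axis=1,
    )
    out[:, 0::2] = np.clip(out[:, 0::2], 0.0, grid.image_width)
    out[:, 1::2] = np.clip(out[:, 1::2], 0.0, grid.image_height)
    return out


def _decode_unclipped(centers: np.ndarray, d: np.ndarray) -> np.ndarray:
    return np.stack(
        [
            centers[:, 0] - d[:, 0],
            centers[:, 1] - d[:, 1],
            centers[:, 0] + d[:, 2],
            centers[:, 1] + d[:, 3],
        ],
        axis=1,
    )


def giou_and_grad(
    pred: np.ndarray, gt: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Generalized IoU of row-paired corner boxes and its gradient with
    respect to the predicted corners."""
    px1, py1, px2, py2 = pred[:, 0], pred[:, 1], pred[:, 2], pred[:, 3]
    gx1, gy1, gx2, gy2 = gt[:, 0], gt[:, 1], gt[:, 2], gt[:, 3]
    iw = np.minimum(px2, gx2) - np.maximum(px1, gx1)
    ih = np.minimum(py2, gy2) - np.maximum(py1, gy1)
    has_i = (iw > 0) & (ih > 0)
    iw_c, ih_c = np.clip(iw, 0, None), np.clip(ih, 0, None)
    inter = iw_c * ih_c
    ap = (px2 - px1) * (py2 - py1)
    ag = (gx2 - gx1) * (gy2 - gy1)
    union = ap + ag - inter
    cw = np.maximum(px2, gx2) - np.minimum(px1, gx1)
    ch = np.maximum(py2, gy2) - np.minimum(py1, gy1)
    chull = cw * ch
    giou = inter / union - (chull - union) / chull

    # dI/dcorner (subgradient 0 at empty intersection / ties)
    dI = np.zeros_like(pred)
    dI[:, 0] = -ih_c * (px1 > gx1) * has_i
    dI[:, 2] = ih_c * (px2 < gx2) * has_i
    dI[:, 1] = -iw_c * (py1 > gy1) * has_i
    dI[:, 3] = iw_c * (py2 < gy2) * has_i
    dAp = np.stack(
        [-(py2 - py1), -(px2 - px1), (py2 - py1), (px2 - px1)], axis=1
    )
    dU = dAp - dI
    dC = np.zeros_like(pred)
    dC[:, 0] = -ch * (px1 < gx1)
    dC[:, 2] = ch * (px2 > gx2)
    dC[:, 1] = -cw * (py1 < gy1)
    dC[:, 3] = cw * (py2 > gy2)
    u2 = union[:, None] ** 2
    c2 = chull[:, None] ** 2
    dG = (dI * union[:, None] - inter[:, None] * dU) / u2 + (
        dU * chull[:, None] - union[:, None] * dC
    ) / c2
    return giou, dG


# ---------------------------------------------------------------------------
# Configuration and model


@dataclass(frozen=True)
class DetectorConfig:
    """Detector hyperparameters shared by both variants."""

    variant: str = "anchor_free"  # or "anchor_based"
    num_classes: int = 3
    stride: int = 8
    backbone_depth: int = 2
    backbone_width: int = 128
    anchor_sizes: tuple[float, ...] | None = None
    anchor_aspects: tuple[float, ...] | None = None
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25
    nms_iou: float = 0.6
    score_floor: float = 0.05
    max_detections: int = 100
    loc_weight_floor: float = 0.3

    def __post_init__(self) -> None:
        if self.variant not in ("anchor_free", "anchor_based"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "anchor_based":
            if self.anchor_sizes is None:
                object.__setattr__(self, "anchor_sizes", (16.0, 32.0, 64.0))
            if self.anchor_aspects is None:
                object.__setattr__(self, "anchor_aspects", (0.5, 1.0, 2.0))
        elif self.anchor_sizes is not None or self.anchor_aspects is not None:
            raise ValueError("anchor fields only apply to the anchor_based variant")

    @property
    def num_anchors(self) -> int:
        if self.variant != "anchor_based":
            return 0
        return len(self.anchor_sizes) * len(self.anchor_aspects)


@dataclass
class Detection:
    """One scored detection; ``delta`` is the localization uncertainty
    (mean predicted per-side Laplace scale normalized by the box
    diagonal)."""

    box: BoundingBox
    class_id: int
    score: float
    delta: float = 0.0
    loc_index: int = -1  # source grid location (teacher bookkeeping)
    reg: np.ndarray | None = None  # predicted (l,t,r,b) at loc_index

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")
        if not np.isfinite(self.delta) or self.delta < 0:
            raise ValueError(f"invalid localization uncertainty {self.delta}")


def extract_features(image: np.ndarray, stride: int) -> np.ndarray:
    """Fixed feature stem: per-cell RGB mean/std pooled over the stride
    window, concatenated over 5x5 neighborhoods at dilations 1 and 3.

    Returns an ``(n_locations, FEATURE_DIM)`` float array.
    """
    h, w = image.shape[:2]
    if h % stride or w % stride:
        raise ShapeError(f"image {w}x{h} not divisible by stride {stride}")
    gh, gw = h // stride, w // stride
    x = image.astype(np.float64) / 255.0
    cells = x.reshape(gh, stride, gw, stride, 3)
    mean = cells.mean(axis=(1, 3))
    std = cells.std(axis=(1, 3))
    stats = np.concatenate([mean, std], axis=2)  # (gh, gw, 6)
    ii = np.arange(gh)[:, None]
    jj = np.arange(gw)[None, :]
    feats = []
    for dil in _STEM_DILATIONS:
        for di in range(-_STEM_OFFSETS, _STEM_OFFSETS + 1):
            for dj in range(-_STEM_OFFSETS, _STEM_OFFSETS + 1):
                si = np.clip(ii + di * dil, 0, gh - 1)
                sj = np.clip(jj + dj * dil, 0, gw - 1)
                feats.append(stats[si, sj])
    out = np.concatenate(feats, axis=2)
    return out.reshape(gh * gw, -1)


class DenseDetector:
    """Single-level dense detector; parameters live in ``self.params``."""

    def __init__(self, config: DetectorConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        a = max(1, config.num_anchors)
        if config.variant == "anchor_free":
            head_dims = {
                "cls": config.num_classes,
                "ctr": 1,
                "reg": 4,
                "unc": 4,
            }
        else:
            head_dims = {
                "cls": a * config.num_classes,
                "reg": a * 4,
                "unc": a * 4,
            }
        prior_logit = -float(np.log((1.0 - _FOCAL_PRIOR) / _FOCAL_PRIOR))
        self.net = MLPWithHeads(
            FEATURE_DIM,
            (config.backbone_width,) * config.backbone_depth,
            head_dims,
            rng,
            head_bias_init={"cls": prior_logit, "reg": 1.0, "unc": 1.2},
        )

    @property
    def params(self) -> dict[str, np.ndarray]:
        return self.net.params

    def clone(self) -> "DenseDetector":
        other = DenseDetector(self.config, seed=0)
        for k, v in self.params.items():
            other.params[k] = v.copy()
        return other

    def grid_for(self, image: np.ndarray) -> FeatureGrid:
        h, w = image.shape[:2]
        return FeatureGrid.for_image(h, w, self.config.stride)

    def forward(self, image: np.ndarray):
        """Head outputs, backward cache and the image's feature grid."""
        grid = self.grid_for(image)
        feats = extract_features(image, self.config.stride)
        outputs, cache = self.net.forward(feats)
        return outputs, cache, grid

    # -- decoding helpers -------------------------------------------------

    def distances(self, reg_logits: np.ndarray) -> np.ndarray:
        """Nonnegative per-side distances via a softplus mapping."""
        return self.config.stride * softplus(reg_logits)

    def scales(self, unc_logits: np.ndarray) -> np.ndarray:
        """Laplace scales (pixels) from the uncertainty head."""
        return np.exp(np.clip(unc_logits, -_UNC_CLIP, _UNC_CLIP))

    def _decode_anchor_deltas(
        self, anchors: np.ndarray, deltas: np.ndarray
    ) -> np.ndarray:
        aw = anchors[:, 2] - anchors[:, 0]
        ah = anchors[:, 3] - anchors[:, 1]
        ax = (anchors[:, 0] + anchors[:, 2]) / 2.0
        ay = (anchors[:, 1] + anchors[:, 3]) / 2.0
        cx = ax + deltas[:, 0] * aw
        cy = ay + deltas[:, 1] * ah
        w = aw * np.exp(np.clip(deltas[:, 2], -4.0, 4.0))
        h = ah * np.exp(np.clip(deltas[:, 3], -4.0, 4.0))
        return np.stack(
            [cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1
        )


# ---------------------------------------------------------------------------
# Losses


@dataclass
class LossComponents:
    classification: float
    regression: float
    centerness: float
    uncertainty: float

    @property
    def total(self) -> float:
        return (
            self.classification
            + self.regression
            + self.centerness
            + self.uncertainty
        )

    def check_finite(self) -> "LossComponents":
        vals = (
            self.classification,
            self.regression,
            self.centerness,
            self.uncertainty,
        )
        if not np.all(np.isfinite(vals)):
            raise FloatingPointError(f"non-finite loss component: {vals}")
        return self


def _focal_and_grad(
    logits: np.ndarray,
    onehot: np.ndarray,
    gamma: float,
    alpha: float,
    row_weight: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Sigmoid focal loss (sum) with per-row weights and its logit grad."""
    p = sigmoid(logits)
    t = onehot
    pt = np.clip(t * p + (1 - t) * (1 - p), 1e-12, 1.0)
    at = t * alpha + (1 - t) * (1 - alpha)
    q = 1.0 - pt
    loss = -(at * q**gamma * np.log(pt))
    dldpt = at * (gamma * q ** (gamma - 1) * np.log(pt) - q**gamma / pt)
    dptdz = (2 * t - 1) * p * (1 - p)
    grad = dldpt * dptdz
    w = row_weight[:, None]
    return float((loss * w).sum()), grad * w


def classification_loss_and_grad(
    cls_logits: np.ndarray,
    labels: np.ndarray,
    loc_weights: np.ndarray,
    config: DetectorConfig,
    normalizer: float,
) -> tuple[float, np.ndarray]:
    """Focal classification loss with detached localization weighting.

    ``loc_weights`` gives each positive location's weight (the IoU between
    its decoded predicted box and the assigned box, floored to keep early
    training alive); background rows have weight 1.
    """
    n, k = cls_logits.shape
    onehot = np.zeros((n, k))
    pos = labels >= 0
    onehot[pos, labels[pos]] = 1.0
    loss, grad = _focal_and_grad(
        cls_logits, onehot, config.focal_gamma, config.focal_alpha, loc_weights
    )
    return loss / normalizer, grad / normalizer


def supervised_loss(
    outputs: dict[str, np.ndarray],
    targets,
    grid: FeatureGrid,
    config: DetectorConfig,
) -> LossComponents:
    """Loss components only (gradient-free view of the training loss)."""
    comps, _ = supervised_loss_and_grads(outputs, targets, grid, config)
    return comps


def supervised_loss_and_grads(
    outputs: dict[str, np.ndarray],
    targets,
    grid: FeatureGrid,
    config: DetectorConfig,
) -> tuple[LossComponents, dict[str, np.ndarray]]:
    """Supervised loss and head-output gradients for one image.

    Anchor-free components: IoU-weighted focal classification, GIoU
    regression, centerness BCE and a per-side Laplace negative log
    likelihood training the uncertainty branch; everything normalized by
    the positive-location count.
    """
    if config.variant == "anchor_based":
        return _anchor_loss_and_grads(outputs, targets, grid, config)
    cls_z, ctr_z = outputs["cls"], outputs["ctr"][:, 0]
    reg_z, unc_z = outputs["reg"], outputs["unc"]
    pos = targets.positive_mask
    n_pos = max(1, int(pos.sum()))
    centers = grid.centers()

    d_pred = config.stride * softplus(reg_z)
    pred_boxes = _decode_unclipped(centers, d_pred)
    gt_boxes = _decode_unclipped(centers, targets.reg)

    loc_w = np.ones(len(cls_z))
    if pos.any():
        ious = _paired_iou(pred_boxes[pos], gt_boxes[pos])
        loc_w[pos] = np.maximum(ious, config.loc_weight_floor)
    cls_loss, cls_grad = classification_loss_and_grad(
        cls_z, targets.labels, loc_w, config, float(n_pos)
    )

    reg_loss, ctr_loss, unc_loss = 0.0, 0.0, 0.0
    reg_grad = np.zeros_like(reg_z)
    ctr_grad = np.zeros_like(ctr_z)
    unc_grad = np.zeros_like(unc_z)
    if pos.any():
        giou, dgiou = giou_and_grad(pred_boxes[pos], gt_boxes[pos])
        reg_loss = float((1.0 - giou).sum()) / n_pos
        dcorner = -dgiou / n_pos
        # corners -> distances -> logits (softplus' = sigmoid)
        ddist = np.stack(
            [-dcorner[:, 0], -dcorner[:, 1], dcorner[:, 2], dcorner[:, 3]],
            axis=1,
        )
        reg_grad[pos] = ddist * config.stride * sigmoid(reg_z[pos])

        p_ctr = sigmoid(ctr_z[pos])
        c_t = targets.centerness[pos]
        ctr_loss = float(
            -(c_t * np.log(np.clip(p_ctr, 1e-12, 1))
              + (1 - c_t) * np.log(np.clip(1 - p_ctr, 1e-12, 1))).sum()
        ) / n_pos
        ctr_grad[pos] = (p_ctr - c_t) / n_pos

        resid = np.abs(targets.reg[pos] - d_pred[pos])  # detached
        u = np.clip(unc_z[pos], -_UNC_CLIP, _UNC_CLIP)
        s = np.exp(u)
        unc_loss = float((resid / s + u).sum()) / (4 * n_pos)
        du = (1.0 - resid / s) / (4 * n_pos)
        du[(unc_z[pos] < -_UNC_CLIP) | (unc_z[pos] > _UNC_CLIP)] = 0.0
        unc_grad[pos] = du

    comps = LossComponents(cls_loss, reg_loss, ctr_loss, unc_loss).check_finite()
    grads = {
        "cls": cls_grad,
        "ctr": ctr_grad[:, None],
        "reg": reg_grad,
        "unc": unc_grad,
    }
    return comps, grads


def _paired_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    iw = np.clip(np.minimum(a[:, 2], b[:, 2]) - np.maximum(a[:, 0], b[:, 0]), 0, None)
    ih = np.clip(np.minimum(a[:, 3], b[:, 3]) - np.maximum(a[:, 1], b[:, 1]), 0, None)
    inter = iw * ih
    aa = np.clip(a[:, 2] - a[:, 0], 0, None) * np.clip(a[:, 3] - a[:, 1], 0, None)
    ab = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = np.maximum(aa + ab - inter, 1e-12)
    return inter / union


def _anchor_loss_and_grads(
    outputs: dict[str, np.ndarray],
    targets: AnchorTargets,
    grid: FeatureGrid,
    config: DetectorConfig,
) -> tuple[LossComponents, dict[str, np.ndarray]]:
    """Single-stage anchor-based loss: focal classification over the
    positive/negative bands (ignored anchors masked out) and GIoU on
    decoded positive anchors; Laplace NLL on per-corner residuals."""
    a = config.num_anchors
    k = config.num_classes
    n = outputs["cls"].shape[0]
    cls_z = outputs["cls"].reshape(n * a, k)
    reg_z = outputs["reg"].reshape(n * a, 4)
    unc_z = outputs["unc"].reshape(n * a, 4)
    anchors = generate_anchors(grid, config.anchor_sizes, config.anchor_aspects)

    pos = targets.status == 1
    ignored = targets.status == -1
    n_pos = max(1, int(pos.sum()))

    det = DenseDetector.__new__(DenseDetector)
    det.config = config
    pred_boxes = det._decode_anchor_deltas(anchors, reg_z)

    loc_w = np.ones(n * a)
    loc_w[ignored] = 0.0
    if pos.any():
        gtb = targets.gt_boxes[targets.assigned[pos]]
        loc_w[pos] = np.maximum(
            _paired_iou(pred_boxes[pos], gtb), config.loc_weight_floor
        )
    cls_loss, cls_grad = classification_loss_and_grad(
        cls_z, targets.labels, loc_w, config, float(n_pos)
    )

    reg_loss, unc_loss = 0.0, 0.0
    reg_grad = np.zeros_like(reg_z)
    unc_grad = np.zeros_like(unc_z)
    if pos.any():
        gtb = targets.gt_boxes[targets.assigned[pos]]
        giou, dgiou = giou_and_grad(pred_boxes[pos], gtb)
        reg_loss = float((1.0 - giou).sum()) / n_pos
        dcorner = -dgiou / n_pos
        # chain through the delta decode
        ap = anchors[pos]
        aw = ap[:, 2] - ap[:, 0]
        ah = ap[:, 3] - ap[:, 1]
        tw = np.clip(reg_z[pos, 2], -4.0, 4.0)
        th = np.clip(reg_z[pos, 3], -4.0, 4.0)
        w = aw * np.exp(tw)
        h = ah * np.exp(th)
        g = np.zeros_like(reg_grad[pos])
        g[:, 0] = (dcorner[:, 0] + dcorner[:, 2]) * aw
        g[:, 1] = (dcorner[:, 1] + dcorner[:, 3]) * ah
        g[:, 2] = (-dcorner[:, 0] + dcorner[:, 2]) * (w / 2.0)
        g[:, 3] = (-dcorner[:, 1] + dcorner[:, 3]) * (h / 2.0)
        g[:, 2] *= (np.abs(reg_z[pos, 2]) < 4.0)
        g[:, 3] *= (np.abs(reg_z[pos, 3]) < 4.0)
        reg_grad[pos] = g

        resid = np.abs(pred_boxes[pos] - gtb)  # detached
        u = np.clip(unc_z[pos], -_UNC_CLIP, _UNC_CLIP)
        s = np.exp(u)
        unc_loss = float((resid / s + u).sum()) / (4 * n_pos)
        du = (1.0 - resid / s) / (4 * n_pos)
        du[(unc_z[pos] < -_UNC_CLIP) | (unc_z[pos] > _UNC_CLIP)] = 0.0
        unc_grad[pos] = du

    comps = LossComponents(cls_loss, reg_loss, 0.0, unc_loss).check_finite()
    grads = {
        "cls": cls_grad.reshape(n, a * k),
        "reg": reg_grad.reshape(n, a * 4),
        "unc": unc_grad.reshape(n, a * 4),
    }
    return comps, grads


# ---------------------------------------------------------------------------
# NMS and inference


def nms(detections: list[Detection], iou_threshold: float) -> list[Detection]:
    """Greedy class-wise non-maximum suppression.

    Processing order is descending score with ties broken by lower input
    index, so the output is independent of input ordering among distinct
    scores.
    """
    if not detections:
        return []
    scores = np.array([d.score for d in detections])
    order = np.lexsort((np.arange(len(detections)), -scores))
    boxes = np.stack([detections[i].box.as_array() for i in order])
    classes = np.array([detections[i].class_id for i in order])
    keep_mask = np.ones(len(order), dtype=bool)
    for i in range(len(order)):
        if not keep_mask[i]:
            continue
        later = np.nonzero(keep_mask & (np.arange(len(order)) > i) & (classes == classes[i]))[0]
        if later.size:
            ious = iou_matrix(boxes[i][None], boxes[later])[0]
            keep_mask[later[ious >= iou_threshold]] = False
    return [detections[order[i]] for i in range(len(order)) if keep_mask[i]]


def infer(
    model: DenseDetector,
    image: np.ndarray,
    score_mode: str = "supervised",
) -> list[Detection]:
    """Run the detector on one image.

    The detection score is the maximum per-class sigmoid probability; in
    the anchor-free variant it is additionally multiplied by the centerness
    probability under ``score_mode="supervised"`` but never under
    ``score_mode="pseudo"`` (the centerness branch has no background
    suppression and is unreliable for pseudo-label ranking).
    """
    if score_mode not in ("supervised", "pseudo"):
        raise ValueError(f"unknown score_mode {score_mode!r}")
    config = model.config
    outputs, _, grid = model.forward(image)
    if config.variant == "anchor_free":
        probs = sigmoid(outputs["cls"])
        scores = probs.max(axis=1)
        classes = probs.argmax(axis=1)
        if score_mode == "supervised":
            scores = scores * sigmoid(outputs["ctr"][:, 0])
        d = model.distances(outputs["reg"])
        boxes = decode_boxes(grid, d)
        scales = model.scales(outputs["unc"])
        loc_index = np.arange(grid.n_locations)
        reg_vecs = d
    else:
        a, k = config.num_anchors, config.num_classes
        n = outputs["cls"].shape[0]
        probs = sigmoid(outputs["cls"].reshape(n * a, k))
        scores = probs.max(axis=1)
        classes = probs.argmax(axis=1)
        anchors = generate_anchors(grid, config.anchor_sizes, config.anchor_aspects)
        boxes = model._decode_anchor_deltas(anchors, outputs["reg"].reshape(n * a, 4))
        boxes[:, 0::2] = np.clip(boxes[:, 0::2], 0.0, grid.image_width)
        boxes[:, 1::2] = np.clip(boxes[:, 1::2], 0.0, grid.image_height)
        scales = model.scales(outputs["unc"].reshape(n * a, 4))
        loc_index = np.repeat(np.arange(n), a)
        reg_vecs = boxes  # corner form doubles as the regression vector

    keep = scores >= config.score_floor
    dets: list[Detection] = []
    for idx in np.nonzero(keep)[0]:
        x1, y1, x2, y2 = boxes[idx]
        if x2 - x1 < 1e-3 or y2 - y1 < 1e-3:
            continue
        diag = float(np.hypot(x2 - x1, y2 - y1))
        dets.append(
            Detection(
                box=BoundingBox(x1, y1, x2, y2, int(classes[idx])),
                class_id=int(classes[idx]),
                score=float(scores[idx]),
                delta=float(scales[idx].mean() / max(diag, 1e-6)),
                loc_index=int(loc_index[idx]),
                reg=reg_vecs[idx].copy(),
            )
        )
    dets = nms(dets, config.nms_iou)
    dets.sort(key=lambda d: -d.score)
    return dets[: config.max_detections]


# ---------------------------------------------------------------------------
# Checkpoints and detection dumps


def save_checkpoint(model: DenseDetector, path: str | Path) -> None:
    """Write config + parameter tensors to a single ``.npz`` file."""
    path = Path(path)
    cfg = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(model.config).items()
    }
    buf = io.BytesIO()
    np.savez(buf, __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
             **model.params)
    path.write_bytes(buf.getvalue())


def load_checkpoint(path: str | Path) -> DenseDetector:
    with np.load(Path(path)) as data:
        cfg = json.loads(bytes(data["__config__"]).decode())
        for key in ("anchor_sizes", "anchor_aspects"):
            if cfg.get(key) is not None:
                cfg[key] = tuple(cfg[key])
        model = DenseDetector(DetectorConfig(**cfg), seed=0)
        for k in model.params:
            model.params[k] = data[k].copy()
    return model


def detections_to_coco_results(
    detections_by_image: dict[int, list[Detection]]
) -> list[dict]:
    """COCO-results records: image_id, 1-based category_id, xywh bbox, score."""
    out = []
    for image_id in sorted(detections_by_image):
        for d in detections_by_image[image_id]:
            x, y, w, h = d.box.as_xywh()
            out.append(
                {
                    "image_id": image_id,
                    "category_id": d.class_id + 1,
                    "bbox": [round(v, 3) for v in (x, y, w, h)],
                    "score": round(d.score, 6),
                }
            )
    return out
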