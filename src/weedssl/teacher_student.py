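"""Teacher-student semi-supervised training engine.

The pipeline: (1) burn-in — supervised training on the labeled subset;
(2) the trained model is duplicated into a teacher/student pair; (3) each
subsequent step the teacher pseudo-labels weakly augmented views of
unlabeled images, the student is optimized on its supervised loss plus
weighted unsupervised classification and regression losses computed on
strongly augmented views of the same images, and the teacher follows the
student through an exponential moving average
``theta_t <- alpha * theta_t + (1 - alpha) * theta_s``.  Only the teacher
is kept for inference.

Pseudo-boxes are ranked by classification score alone (the centerness
branch has no background supervision and is excluded from pseudo-label
scoring).  The unsupervised regression loss is gated per pseudo-instance:
an instance contributes the L1 distance between teacher and student
regression predictions only when the teacher's localization uncertainty
undercuts the student's by at least a margin ``sigma``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageFilter

from ._nn import SGDMomentum, sigmoid, softplus
from .boxes import BoundingBox
from .detector_core import (
    DenseDetector,
    Detection,
    DetectorConfig,
    FeatureGrid,
    LossComponents,
    assign_targets_anchor_based,
    assign_targets_anchor_free,
    classification_loss_and_grad,
    generate_anchors,
    infer,
    supervised_loss_and_grads,
    _decode_unclipped,
    _paired_iou,
)
from .eval_metrics import evaluate_detections
from .scene_forge import AnnotatedImage

logger = logging.getLogger(__name__)

_GRAD_CLIP_NORM = 5.0  # global-norm clip guarding rare focal-loss spikes


class ConfigurationError(ValueError):
    """Invalid training configuration."""


# ---------------------------------------------------------------------------
# Types


@dataclass
class EMAState:
    """Paired teacher/student parameter collections plus the EMA
    coefficient ``alpha``; ``alpha=1`` freezes the teacher, ``alpha=0``
    copies the student."""

    teacher: dict[str, np.ndarray]
    student: dict[str, np.ndarray]
    alpha: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha {self.alpha} outside [0, 1]")
        self.validate()

    def validate(self) -> None:
        if set(self.teacher) != set(self.student):
            raise ValueError("teacher/student parameter names differ")
        for k in self.teacher:
            if self.teacher[k].shape != self.student[k].shape:
                raise ValueError(f"shape mismatch for parameter {k!r}")


@dataclass
class PseudoLabelSet:
    """Teacher-produced boxes for one unlabeled image (post-NMS, scores
    all at or above the threshold ``tau``)."""

    image_id: int
    boxes: list[Detection]
    tau: float

    def __post_init__(self) -> None:
        for d in self.boxes:
            if d.score < self.tau - 1e-12:
                raise ValueError("pseudo-box below the confidence threshold")

    def as_bounding_boxes(self) -> list[BoundingBox]:
        return [d.box for d in self.boxes]


@dataclass
class AugmentationRecord:
    """Shared weak-view geometry plus the strong view's photometric
    parameters.  Applying the geometry to a box then inverting it recovers
    the original box."""

    flip: bool
    scale_x: float
    scale_y: float
    orig_size: tuple[int, int]  # (width, height)
    new_size: tuple[int, int]
    strong: dict = field(default_factory=dict)

    def apply_boxes(self, boxes: list[BoundingBox]) -> list[BoundingBox]:
        out = []
        nw, _ = self.new_size
        for b in boxes:
            x1, y1 = b.x_min * self.scale_x, b.y_min * self.scale_y
            x2, y2 = b.x_max * self.scale_x, b.y_max * self.scale_y
            if self.flip:
                x1, x2 = nw - x2, nw - x1
            out.append(BoundingBox(x1, y1, x2, y2, b.class_id))
        return out

    def invert_boxes(self, boxes: list[BoundingBox]) -> list[BoundingBox]:
        out = []
        nw, _ = self.new_size
        for b in boxes:
            x1, x2 = b.x_min, b.x_max
            if self.flip:
                x1, x2 = nw - x2, nw - x1
            out.append(
                BoundingBox(
                    x1 / self.scale_x,
                    b.y_min / self.scale_y,
                    x2 / self.scale_x,
                    b.y_max / self.scale_y,
                    b.class_id,
                )
            )
        return out


@dataclass
class UnsupRegressionInputs:
    """Per-instance teacher/student regression predictions and
    localization uncertainties entering the gated unsupervised regression
    loss."""

    teacher_reg: np.ndarray  # (M, 4)
    student_reg: np.ndarray  # (M, 4)
    teacher_delta: np.ndarray  # (M,)
    student_delta: np.ndarray  # (M,)
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma {self.sigma} must be >= 0")
        for arr in (
            self.teacher_reg,
            self.student_reg,
            self.teacher_delta,
            self.student_delta,
        ):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite value in regression inputs")


@dataclass
class TrainSchedule:
    """Desk-scale training schedule.

    The batch composition mirrors the labeled/unlabeled half-batch scheme
    (field preset 4+4; desk default 2+2).  ``lambda_u`` weights the
    unsupervised losses, ``tau`` is the pseudo-label confidence threshold,
    ``sigma`` the uncertainty margin and ``alpha`` the EMA coefficient.
    """

    burn_in_iters: int = 400
    total_iters: int = 2000
    n_labeled: int = 2
    n_unlabeled: int = 2
    lr: float = 0.02
    momentum: float = 0.9
    lambda_u: float = 1.0
    tau: float = 0.7
    sigma: float = 0.1
    alpha: float = 0.99
    eval_interval: int = 100
    weak_scale_range: tuple[int, int] = (96, 160)

    def __post_init__(self) -> None:
        if self.burn_in_iters >= self.total_iters:
            raise ConfigurationError("burn-in must be shorter than total")
        if self.n_labeled < 1:
            raise ConfigurationError("need at least 1 labeled image per batch")
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")


# ---------------------------------------------------------------------------
# EMA


def ema_update(state: EMAState) -> EMAState:
    """One EMA step: ``theta_t <- alpha * theta_t + (1 - alpha) * theta_s``
    elementwise; the student is untouched."""
    state.validate()
    a = state.alpha
    for k in state.teacher:
        state.teacher[k] *= a
        state.teacher[k] += (1.0 - a) * state.student[k]
    return state


def duplicate_to_student(teacher: DenseDetector, alpha: float = 0.99) -> EMAState:
    """Duplicate a trained model into an elementwise-identical
    teacher/student pair (the argument becomes the student; the teacher is
    a deep copy)."""
    teacher_params = {k: v.copy() for k, v in teacher.params.items()}
    return EMAState(teacher=teacher_params, student=teacher.params, alpha=alpha)


# ---------------------------------------------------------------------------
# Augmentation


def weak_augment(
    image: np.ndarray,
    boxes: list[BoundingBox],
    rng: np.random.Generator,
    scale_range: tuple[int, int] = (96, 160),
    stride: int = 8,
) -> tuple[np.ndarray, list[BoundingBox], AugmentationRecord]:
    """Weak geometric view: horizontal flip with probability 0.5 and a
    shorter-side resize to a stride multiple drawn from ``scale_range``."""
    h, w = image.shape[:2]
    lo, hi = scale_range
    choices = np.arange(int(np.ceil(lo / stride)) * stride, hi + 1, stride)
    target = int(rng.choice(choices))
    sf = target / min(h, w)
    nw = max(stride, int(round(w * sf / stride)) * stride)
    nh = max(stride, int(round(h * sf / stride)) * stride)
    flip = bool(rng.random() < 0.5)
    view = np.asarray(
        Image.fromarray(image).resize((nw, nh), Image.BILINEAR), dtype=np.uint8
    )
    if flip:
        view = view[:, ::-1].copy()
    record = AugmentationRecord(
        flip=flip,
        scale_x=nw / w,
        scale_y=nh / h,
        orig_size=(w, h),
        new_size=(nw, nh),
    )
    return view, record.apply_boxes(boxes), record


def strong_augment(
    weak_view: np.ndarray,
    record: AugmentationRecord,
    rng: np.random.Generator,
    p_gray: float = 0.2,
    p_blur: float = 0.5,
    max_cutouts: int = 5,
) -> np.ndarray:
    """Photometric + cutout perturbation on top of the weak geometry.

    Box coordinates are unchanged between the weak (teacher) and strong
    (student) views, so pseudo-boxes transfer without remapping.  The drawn
    parameters are stored on ``record.strong``.
    """
    img = weak_view.astype(np.float64)
    h, w = img.shape[:2]
    params: dict = {}
    params["gray"] = bool(rng.random() < p_gray)
    if params["gray"]:
        luma = img @ np.array([0.299, 0.587, 0.114])
        img = np.repeat(luma[:, :, None], 3, axis=2)
    params["jitter"] = {
        "brightness": float(rng.uniform(0.7, 1.3)),
        "contrast": float(rng.uniform(0.7, 1.3)),
        "shift": float(rng.uniform(-20, 20)),
    }
    img = img * params["jitter"]["brightness"] + params["jitter"]["shift"]
    mean = img.mean()
    img = (img - mean) * params["jitter"]["contrast"] + mean
    params["blur"] = None
    if rng.random() < p_blur:
        radius = float(rng.uniform(0.5, 1.5))
        params["blur"] = radius
        img = np.asarray(
            Image.fromarray(np.clip(img, 0, 255).astype(np.uint8)).filter(
                ImageFilter.GaussianBlur(radius)
            ),
            dtype=np.float64,
        )
    n_cut = int(rng.integers(1, max_cutouts + 1))
    params["cutouts"] = []
    for _ in range(n_cut):
        cw = int(rng.uniform(0.08, 0.25) * w)
        ch = int(rng.uniform(0.08, 0.25) * h)
        x0 = int(rng.integers(0, max(1, w - cw)))
        y0 = int(rng.integers(0, max(1, h - ch)))
        img[y0 : y0 + ch, x0 : x0 + cw] = 127.0
        params["cutouts"].append((x0, y0, cw, ch))
    record.strong = params
    return np.clip(img, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Pseudo-labels and unsupervised losses


def generate_pseudo_labels(
    teacher: DenseDetector,
    weak_view: np.ndarray,
    tau: float,
    image_id: int = -1,
) -> PseudoLabelSet:
    """Teacher inference on the weak view, ranked by classification score
    only, thresholded at ``tau``.  No gradient can reach the teacher (the
    forward pass does not record one)."""
    dets = infer(teacher, weak_view, score_mode="pseudo")
    kept = [d for d in dets if d.score >= tau]
    return PseudoLabelSet(image_id=image_id, boxes=kept, tau=tau)


def unsup_regression_loss(inputs: UnsupRegressionInputs) -> float:
    """Gated unsupervised regression loss.

    Instance ``i`` contributes ``||d_t^i - d_s^i||_1`` iff
    ``delta_t^i + sigma <= delta_s^i`` (the boundary passes), else 0; the
    result is the sum over instances.  Teacher quantities are constants.
    """
    gate = inputs.teacher_delta + inputs.sigma <= inputs.student_delta
    diffs = np.abs(inputs.teacher_reg - inputs.student_reg).sum(axis=1)
    return float(diffs[gate].sum())


def unsup_regression_gate(inputs: UnsupRegressionInputs) -> np.ndarray:
    """Boolean pass/fail of the uncertainty gate per instance."""
    return inputs.teacher_delta + inputs.sigma <= inputs.student_delta


def unsup_classification_loss(
    student_outputs: dict[str, np.ndarray],
    pseudo: PseudoLabelSet,
    grid: FeatureGrid,
    config: DetectorConfig,
) -> float:
    """Focal classification loss against hard pseudo-labels with detached
    IoU localization weighting — identical machinery to the supervised
    classification component, so exact pseudo-boxes reproduce the
    supervised value."""
    loss, _ = _unsup_classification_loss_and_grad(
        student_outputs, pseudo, grid, config
    )
    return loss


def _unsup_classification_loss_and_grad(
    student_outputs: dict[str, np.ndarray],
    pseudo: PseudoLabelSet,
    grid: FeatureGrid,
    config: DetectorConfig,
) -> tuple[float, np.ndarray]:
    boxes = pseudo.as_bounding_boxes()
    if config.variant == "anchor_free":
        targets = assign_targets_anchor_free(boxes, grid)
        pos = targets.positive_mask
        n_pos = max(1, int(pos.sum()))
        loc_w = np.ones(grid.n_locations)
        if pos.any():
            d_pred = config.stride * softplus(student_outputs["reg"])
            pred_boxes = _decode_unclipped(grid.centers(), d_pred)
            gt_boxes = _decode_unclipped(grid.centers(), targets.reg)
            loc_w[pos] = np.maximum(
                _paired_iou(pred_boxes[pos], gt_boxes[pos]),
                config.loc_weight_floor,
            )
        return classification_loss_and_grad(
            student_outputs["cls"], targets.labels, loc_w, config, float(n_pos)
        )
    # anchor-based: IoU-band assignment against pseudo-boxes
    anchors = generate_anchors(grid, config.anchor_sizes, config.anchor_aspects)
    targets = assign_targets_anchor_based(boxes, anchors)
    a, k = config.num_anchors, config.num_classes
    n = student_outputs["cls"].shape[0]
    cls_z = student_outputs["cls"].reshape(n * a, k)
    pos = targets.positive_mask
    n_pos = max(1, int(pos.sum()))
    loc_w = np.ones(n * a)
    loc_w[targets.status == -1] = 0.0
    loss, grad = classification_loss_and_grad(
        cls_z, targets.labels, loc_w, config, float(n_pos)
    )
    return loss, grad.reshape(n, a * k)


# ---------------------------------------------------------------------------
# Training loops


def _clip_grads(grads: dict[str, np.ndarray]) -> None:
    total = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
    if total > _GRAD_CLIP_NORM:
        scale = _GRAD_CLIP_NORM / total
        for g in grads.values():
            g *= scale


def _accumulate(dst: dict[str, np.ndarray], src: dict[str, np.ndarray], w: float) -> None:
    for k, g in src.items():
        if k in dst:
            dst[k] += w * g
        else:
            dst[k] = w * g


def _supervised_image_grads(
    model: DenseDetector, view: np.ndarray, boxes: list[BoundingBox]
) -> tuple[LossComponents, dict[str, np.ndarray]]:
    outputs, cache, grid = model.forward(view)
    if model.config.variant == "anchor_free":
        targets = assign_targets_anchor_free(boxes, grid)
    else:
        anchors = generate_anchors(
            grid, model.config.anchor_sizes, model.config.anchor_aspects
        )
        targets = assign_targets_anchor_based(boxes, anchors)
    comps, head_grads = supervised_loss_and_grads(
        outputs, targets, grid, model.config
    )
    return comps, model.net.backward(cache, head_grads)


def train_supervised(
    images: list[AnnotatedImage],
    schedule: TrainSchedule,
    config: DetectorConfig,
    seed: int = 0,
    iterations: int | None = None,
    batch_size: int | None = None,
    val_images: list[AnnotatedImage] | None = None,
    history: list[dict] | None = None,
) -> DenseDetector:
    """Supervised training on annotated images (also the burn-in phase).

    With ``val_images`` given, the parameters with the best validation
    mAP@[0.5:0.95] (evaluated every ``schedule.eval_interval`` iterations
    and at the end) are restored before returning.
    """
    if not images:
        raise ConfigurationError("supervised training requires >= 1 image")
    iterations = schedule.total_iters if iterations is None else iterations
    batch_size = (
        schedule.n_labeled + schedule.n_unlabeled
        if batch_size is None
        else batch_size
    )
    rng = np.random.default_rng(seed)
    model = DenseDetector(config, seed=int(rng.integers(2**31)))
    if iterations == 0:
        logger.warning("0-iteration schedule: returning a random-init model")
        return model
    opt = SGDMomentum(schedule.lr, schedule.momentum)
    best = (-1.0, None)
    for it in range(1, iterations + 1):
        idx = rng.integers(0, len(images), size=batch_size)
        grads: dict[str, np.ndarray] = {}
        total = 0.0
        for i in idx:
            im = images[int(i)]
            view, tboxes, _ = weak_augment(
                im.pixels, im.annotations, rng,
                schedule.weak_scale_range, config.stride,
            )
            comps, g = _supervised_image_grads(model, view, tboxes)
            total += comps.total
            _accumulate(grads, g, 1.0 / batch_size)
        _clip_grads(grads)
        opt.step(model.params, grads)
        if history is not None:
            history.append({"iteration": it, "loss": total / batch_size, "phase": "supervised"})
        if val_images and (it % schedule.eval_interval == 0 or it == iterations):
            score = _validation_map(model, val_images)
            if score > best[0]:
                best = (score, {k: v.copy() for k, v in model.params.items()})
    if val_images and best[1] is not None:
        for k in model.params:
            model.params[k] = best[1][k]
    return model


def burn_in(
    labeled: list[AnnotatedImage],
    schedule: TrainSchedule,
    config: DetectorConfig,
    seed: int = 0,
    history: list[dict] | None = None,
) -> DenseDetector:
    """Supervised-only initial phase producing the initial teacher."""
    return train_supervised(
        labeled,
        schedule,
        config,
        seed=seed,
        iterations=schedule.burn_in_iters,
        history=history,
    )


def _validation_map(model: DenseDetector, images: list[AnnotatedImage]) -> float:
    dets = {im.image_id: infer(model, im.pixels) for im in images}
    gts = {im.image_id: im.annotations for im in images}
    try:
        report = evaluate_detections(dets, gts, model.config.num_classes)
        return report.map_50_95
    except Exception:  # no evaluable class yet
        return 0.0


def _teacher_view(state: EMAState, config: DetectorConfig) -> DenseDetector:
    t = DenseDetector(config, seed=0)
    for k in t.params:
        t.params[k] = state.teacher[k]
    return t


def train_semi_supervised(
    labeled: list[AnnotatedImage],
    unlabeled: list[AnnotatedImage],
    schedule: TrainSchedule,
    config: DetectorConfig,
    seed: int = 0,
    val_images: list[AnnotatedImage] | None = None,
    log_path: str | Path | None = None,
) -> tuple[DenseDetector, list[dict]]:
    """Full teacher-student run; returns the retained teacher and the
    per-iteration history.

    With no unlabeled images the trajectory reduces to supervised training
    of the student (the teacher still tracks it via EMA); with
    ``lambda_u=0`` the student's gradients equal the supervised-only ones.
    """
    if not labeled:
        raise ConfigurationError("semi-supervised training requires labeled images")
    history: list[dict] = []
    rng = np.random.default_rng(seed)
    model = train_supervised(
        labeled,
        schedule,
        config,
        seed=int(rng.integers(2**31)),
        iterations=schedule.burn_in_iters,
        history=history,
    )
    state = duplicate_to_student(model, alpha=schedule.alpha)
    teacher = _teacher_view(state, config)
    opt = SGDMomentum(schedule.lr, schedule.momentum)
    best = (-1.0, None)
    for it in range(schedule.burn_in_iters + 1, schedule.total_iters + 1):
        grads: dict[str, np.ndarray] = {}
        sup_total, unsup_cls_total, unsup_reg_total = 0.0, 0.0, 0.0
        n_pseudo, n_gate_pass, n_gate_all = 0, 0, 0

        li = rng.integers(0, len(labeled), size=schedule.n_labeled)
        for i in li:
            im = labeled[int(i)]
            view, tboxes, _ = weak_augment(
                im.pixels, im.annotations, rng,
                schedule.weak_scale_range, config.stride,
            )
            comps, g = _supervised_image_grads(model, view, tboxes)
            sup_total += comps.total
            _accumulate(grads, g, 1.0 / schedule.n_labeled)

        if unlabeled and schedule.n_unlabeled > 0:
            ui = rng.integers(0, len(unlabeled), size=schedule.n_unlabeled)
            for i in ui:
                im = unlabeled[int(i)]
                weak_view, _, record = weak_augment(
                    im.pixels, [], rng,
                    schedule.weak_scale_range, config.stride,
                )
                pseudo = generate_pseudo_labels(
                    teacher, weak_view, schedule.tau, image_id=im.image_id
                )
                n_pseudo += len(pseudo.boxes)
                strong_view = strong_augment(weak_view, record, rng)
                if not pseudo.boxes:
                    # an image in which the teacher found nothing confident
                    # contributes no unsupervised signal (an all-background
                    # push from an empty pseudo set collapses self-training)
                    continue
                outputs, cache, grid = model.forward(strong_view)
                u_cls, cls_grad = _unsup_classification_loss_and_grad(
                    outputs, pseudo, grid, config
                )
                head_grads = {"cls": cls_grad}
                u_reg = 0.0
                if pseudo.boxes and config.variant == "anchor_free":
                    u_reg, reg_grad, passed = _unsup_reg_grads_anchor_free(
                        model, outputs, pseudo, schedule.sigma
                    )
                    head_grads["reg"] = reg_grad
                    n_gate_pass += passed
                    n_gate_all += len(pseudo.boxes)
                unsup_cls_total += u_cls
                unsup_reg_total += u_reg
                if not np.isfinite(u_cls + u_reg):
                    raise FloatingPointError("non-finite unsupervised loss")
                g = model.net.backward(cache, head_grads)
                _accumulate(
                    grads, g, schedule.lambda_u / max(1, schedule.n_unlabeled)
                )

        _clip_grads(grads)
        before = _param_hash(state.teacher)
        opt.step(model.params, grads)
        assert _param_hash(state.teacher) == before, "teacher moved during student update"
        ema_update(state)

        entry = {
            "iteration": it,
            "phase": "semi",
            "sup_loss": sup_total / schedule.n_labeled,
            "unsup_cls_loss": unsup_cls_total / max(1, schedule.n_unlabeled),
            "unsup_reg_loss": unsup_reg_total / max(1, schedule.n_unlabeled),
            "n_pseudo": n_pseudo,
            "gate_pass_frac": (n_gate_pass / n_gate_all) if n_gate_all else 0.0,
        }
        history.append(entry)
        if val_images and (
            it % schedule.eval_interval == 0 or it == schedule.total_iters
        ):
            score = _validation_map(teacher, val_images)
            if score > best[0]:
                best = (score, {k: v.copy() for k, v in state.teacher.items()})
    if val_images and best[1] is not None:
        for k in teacher.params:
            teacher.params[k] = best[1][k]
    if log_path is not None:
        with open(log_path, "w") as fh:
            for entry in history:
                fh.write(json.dumps(entry) + "\n")
    return teacher, history


def _param_hash(params: dict[str, np.ndarray]) -> int:
    return hash(tuple(hash(p.tobytes()) for _, p in sorted(params.items())))


def _unsup_reg_grads_anchor_free(
    student: DenseDetector,
    outputs: dict[str, np.ndarray],
    pseudo: PseudoLabelSet,
    sigma: float,
) -> tuple[float, np.ndarray, int]:
    """Eq-2-style gated L1 between teacher and student regression at the
    pseudo-boxes' source locations; gradients flow to the student's
    regression head only.  Normalized by the pseudo-instance count."""
    locs = np.array([d.loc_index for d in pseudo.boxes], dtype=np.int64)
    teacher_reg = np.stack([d.reg for d in pseudo.boxes])
    teacher_delta = np.array([d.delta for d in pseudo.boxes])
    reg_z = outputs["reg"][locs]
    student_reg = student.config.stride * softplus(reg_z)
    scales = student.scales(outputs["unc"][locs])
    diags = np.array([max(d.box.diagonal, 1e-6) for d in pseudo.boxes])
    student_delta = scales.mean(axis=1) / diags
    inputs = UnsupRegressionInputs(
        teacher_reg, student_reg, teacher_delta, student_delta, sigma
    )
    gate = unsup_regression_gate(inputs)
    m = len(pseudo.boxes)
    loss = unsup_regression_loss(inputs) / m
    grad = np.zeros_like(outputs["reg"])
    if gate.any():
        dl = np.sign(student_reg - teacher_reg) * gate[:, None] / m
        np.add.at(
            grad, locs, dl * student.config.stride * sigmoid(reg_z)
        )
    return loss, grad, int(gate.sum())
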