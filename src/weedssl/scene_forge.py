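"""Synthetic annotated weed scenes, dataset splitting and COCO-dialect I/O.

The generator emulates the statistical structure of small field-weed
detection datasets: a handful of classes (3- and 12-class presets), one to
ten boxes per image with a rare crowded tail, strong class imbalance and a
cluttered natural background.  Each class is rendered as a parametric shape
motif (ellipse, star, lobed rosette, ...) with a per-class base hue plus
per-instance jitter in scale, rotation, hue and texture, so classes are
learnable by a small detector without being trivially separable.

All randomness flows through a single :class:`numpy.random.Generator`
seeded from :class:`SceneConfig`, so an identical seed and config produce a
byte-identical dataset.
"""

from __future__ import annotations

import colorsys
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .boxes import BoundingBox


class SceneConfigError(ValueError):
    """Invalid scene-generator configuration."""


class SplitError(ValueError):
    """Invalid dataset split request."""


class CocoFormatError(ValueError):
    """Malformed COCO-dialect file; message names the offending record."""


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class BoxCountLaw:
    """Per-image box-count distribution: truncated geometric bulk + rare
    crowded tail.

    The bulk is a geometric distribution truncated to
    ``[typical_low, typical_high]`` (success probability ``geom_p``), giving
    mostly 1-3 boxes per image; with probability ``crowded_prob`` the count
    is instead drawn uniformly from ``[crowded_low, crowded_high]``.
    """

    typical_low: int = 1
    typical_high: int = 10
    geom_p: float = 0.45
    crowded_prob: float = 0.01
    crowded_low: int = 11
    crowded_high: int = 25

    def __post_init__(self) -> None:
        if not (1 <= self.typical_low <= self.typical_high):
            raise SceneConfigError("invalid typical box-count range")
        if not (0.0 <= self.crowded_prob < 1.0):
            raise SceneConfigError("crowded_prob must be in [0, 1)")
        if not (0.0 < self.geom_p < 1.0):
            raise SceneConfigError("geom_p must be in (0, 1)")
        if self.crowded_low > self.crowded_high:
            raise SceneConfigError("invalid crowded box-count range")

    def pmf(self, k: int) -> float:
        """Probability of drawing exactly ``k`` boxes."""
        p = 0.0
        if self.typical_low <= k <= self.typical_high:
            ks = np.arange(self.typical_low, self.typical_high + 1)
            w = (1.0 - self.geom_p) ** (ks - self.typical_low)
            p += (1.0 - self.crowded_prob) * (
                (1.0 - self.geom_p) ** (k - self.typical_low) / w.sum()
            )
        if self.crowded_low <= k <= self.crowded_high:
            p += self.crowded_prob / (self.crowded_high - self.crowded_low + 1)
        return float(p)

    def sample(self, rng: np.random.Generator) -> int:
        if rng.random() < self.crowded_prob:
            return int(rng.integers(self.crowded_low, self.crowded_high + 1))
        ks = np.arange(self.typical_low, self.typical_high + 1)
        w = (1.0 - self.geom_p) ** (ks - self.typical_low)
        return int(rng.choice(ks, p=w / w.sum()))


#: Class-name presets matching common cotton-field weed taxa.
CLASS_NAMES_3 = ("carpetweed", "morning_glory", "palmer_amaranth")
CLASS_NAMES_12 = (
    "waterhemp",
    "morning_glory",
    "purslane",
    "spotted_spurge",
    "carpetweed",
    "ragweed",
    "eclipta",
    "prickly_sida",
    "palmer_amaranth",
    "sicklepod",
    "goosegrass",
    "cutleaf_groundcherry",
)

# Shape motif per class index: (shape kind, params, base hue, saturation,
# texture kind).  Hues are spread so the first three classes are maximally
# distinct; textures modulate pixel value so class != flat color blob.
_MOTIFS: list[dict] = [
    {"kind": "lobed", "k": 6, "amp": 0.45, "hue": 0.16, "sat": 0.85, "tex": "speckle"},
    {"kind": "ellipse", "ecc": 0.55, "hue": 0.75, "sat": 0.70, "tex": "none"},
    {"kind": "star", "k": 5, "inner": 0.45, "hue": 0.98, "sat": 0.80, "tex": "speckle"},
    {"kind": "blade", "ecc": 0.30, "hue": 0.33, "sat": 0.90, "tex": "stripes"},
    {"kind": "poly", "k": 3, "hue": 0.08, "sat": 0.90, "tex": "none"},
    {"kind": "cross", "arm": 0.38, "hue": 0.55, "sat": 0.75, "tex": "speckle"},
    {"kind": "lobed", "k": 4, "amp": 0.55, "hue": 0.85, "sat": 0.65, "tex": "stripes"},
    {"kind": "poly", "k": 5, "hue": 0.45, "sat": 0.80, "tex": "speckle"},
    {"kind": "star", "k": 7, "inner": 0.60, "hue": 0.12, "sat": 0.60, "tex": "none"},
    {"kind": "ellipse", "ecc": 0.95, "hue": 0.62, "sat": 0.95, "tex": "stripes"},
    {"kind": "poly", "k": 4, "hue": 0.02, "sat": 0.55, "tex": "speckle"},
    {"kind": "lobed", "k": 8, "amp": 0.30, "hue": 0.28, "sat": 0.50, "tex": "none"},
]


def default_class_weights(num_classes: int) -> tuple[float, ...]:
    """Imbalanced sampling weights: geometric decay, most-frequent first."""
    w = 0.72 ** np.arange(num_classes)
    return tuple((w / w.sum()).tolist())


@dataclass(frozen=True)
class SceneConfig:
    """Controls the synthetic scene generator.

    Parameters
    ----------
    num_classes
        Number of weed categories (3- and 12-class presets carry names).
    image_size
        ``(width, height)`` in pixels.  Desk-scale default 128 x 128.
    box_count_law
        Per-image box-count distribution.
    class_weights
        Per-class sampling weights; ``None`` uses a geometric-decay
        imbalance profile.
    object_scale_range
        Object radius as a fraction of the shorter image side (log-uniform).
    clutter_blobs
        Number of dull background clutter blobs per image.
    seed
        Generator seed; identical seed + config gives identical bytes.
    """

    num_classes: int = 3
    image_size: tuple[int, int] = (128, 128)
    box_count_law: BoxCountLaw = field(default_factory=BoxCountLaw)
    class_weights: tuple[float, ...] | None = None
    object_scale_range: tuple[float, float] = (0.08, 0.22)
    clutter_blobs: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_classes < 1:
            raise SceneConfigError("num_classes must be >= 1")
        w, h = self.image_size
        if w < 32 or h < 32:
            raise SceneConfigError(f"image_size {self.image_size} too small")
        if self.class_weights is not None:
            cw = np.asarray(self.class_weights, dtype=float)
            if cw.size != self.num_classes:
                raise SceneConfigError(
                    "class_weights length must equal num_classes"
                )
            if cw.size == 0 or np.any(cw < 0) or not np.any(cw > 0):
                raise SceneConfigError(
                    "class_weights must be nonnegative with at least one positive"
                )
        lo, hi = self.object_scale_range
        if not (0.0 < lo <= hi < 0.5):
            raise SceneConfigError("object_scale_range must satisfy 0 < lo <= hi < 0.5")

    @property
    def class_names(self) -> tuple[str, ...]:
        if self.num_classes == 3:
            return CLASS_NAMES_3
        if self.num_classes == 12:
            return CLASS_NAMES_12
        return tuple(f"class_{i}" for i in range(self.num_classes))

    def weights(self) -> np.ndarray:
        if self.class_weights is None:
            w = np.asarray(default_class_weights(self.num_classes))
        else:
            w = np.asarray(self.class_weights, dtype=float)
        return w / w.sum()


@dataclass
class AnnotatedImage:
    """An image with its ground-truth boxes."""

    image_id: int
    pixels: np.ndarray  # (H, W, 3) uint8
    annotations: list[BoundingBox]

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    def validate(self) -> None:
        h, w = self.pixels.shape[:2]
        for k, b in enumerate(self.annotations):
            if b.x_min < 0 or b.y_min < 0 or b.x_max > w or b.y_max > h:
                raise ValueError(
                    f"annotation {k} of image {self.image_id} out of bounds"
                )


# ---------------------------------------------------------------------------
# Rendering


def _shape_polygon(motif: dict, radius: float, rot: float, rng: np.random.Generator):
    """Polygon vertices (centered at origin) for one motif instance."""
    kind = motif["kind"]
    if kind == "poly":
        theta = np.linspace(0.0, 2 * np.pi, motif["k"], endpoint=False)
        r = np.full_like(theta, radius)
    elif kind == "star":
        k = motif["k"]
        theta = np.linspace(0.0, 2 * np.pi, 2 * k, endpoint=False)
        r = np.where(np.arange(2 * k) % 2 == 0, radius, radius * motif["inner"])
    elif kind == "lobed":
        theta = np.linspace(0.0, 2 * np.pi, 64, endpoint=False)
        amp = motif["amp"]
        r = radius * (1.0 - amp + amp * np.cos(motif["k"] * theta / 2.0) ** 2)
    elif kind in ("ellipse", "blade"):
        theta = np.linspace(0.0, 2 * np.pi, 48, endpoint=False)
        ecc = motif["ecc"]
        r = radius * ecc / np.sqrt(
            (ecc * np.cos(theta)) ** 2 + np.sin(theta) ** 2
        )
    elif kind == "cross":
        a = motif["arm"]
        pts = np.array(
            [
                (1, a), (a, a), (a, 1), (-a, 1), (-a, a), (-1, a),
                (-1, -a), (-a, -a), (-a, -1), (a, -1), (a, -a), (1, -a),
            ],
            dtype=float,
        ) * radius
        theta = np.arctan2(pts[:, 1], pts[:, 0])
        r = np.hypot(pts[:, 0], pts[:, 1])
    else:  # pragma: no cover - motif table is fixed
        raise SceneConfigError(f"unknown shape kind {kind!r}")
    # slight radial jitter so instances are not perfectly congruent
    r = r * (1.0 + 0.06 * rng.standard_normal(r.shape))
    x = r * np.cos(theta + rot)
    y = r * np.sin(theta + rot)
    return np.stack([x, y], axis=1)


def _background(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Cluttered earthy background: low-frequency color field + speckle."""
    w, h = config.image_size
    base = np.array([96.0, 84.0, 62.0])  # dry-soil brown
    coarse = rng.standard_normal((6, 6, 3)) * 22.0
    img = np.asarray(
        Image.fromarray(
            np.clip(base + coarse, 0, 255).astype(np.uint8)
        ).resize((w, h), Image.BILINEAR),
        dtype=np.float64,
    )
    img = img + rng.standard_normal((h, w, 3)) * 7.0
    # dull clutter blobs (stones / residue), never in a class motif hue band
    draw_img = Image.new("L", (w, h), 0)
    draw = ImageDraw.Draw(draw_img)
    for _ in range(config.clutter_blobs):
        cx, cy = rng.uniform(0, w), rng.uniform(0, h)
        r = rng.uniform(0.02, 0.06) * min(w, h)
        draw.ellipse([cx - r, cy - r, cx + r, cy + r], fill=255)
        mask = np.asarray(draw_img, dtype=bool)
        tone = rng.uniform(50, 130)
        img[mask] = 0.5 * img[mask] + 0.5 * np.array([tone, tone * 0.95, tone * 0.8])
        draw.rectangle([0, 0, w, h], fill=0)
    return np.clip(img, 0, 255)


def _render_object(
    img: np.ndarray,
    class_id: int,
    config: SceneConfig,
    rng: np.random.Generator,
) -> BoundingBox | None:
    """Paint one motif instance; return its tight box or None on failure."""
    w, h = config.image_size
    motif = _MOTIFS[class_id % len(_MOTIFS)]
    lo, hi = config.object_scale_range
    radius = math.exp(rng.uniform(math.log(lo), math.log(hi))) * min(w, h)
    rot = rng.uniform(0, 2 * np.pi)
    margin = radius * 0.6
    cx = rng.uniform(margin, w - margin)
    cy = rng.uniform(margin, h - margin)
    pts = _shape_polygon(motif, radius, rot, rng) + np.array([cx, cy])

    mask_img = Image.new("L", (w, h), 0)
    ImageDraw.Draw(mask_img).polygon(
        [tuple(p) for p in pts], fill=255
    )
    mask = np.asarray(mask_img, dtype=bool)
    if mask.sum() < 12:
        return None
    ys, xs = np.nonzero(mask)
    x0, x1 = int(xs.min()), int(xs.max()) + 1
    y0, y1 = int(ys.min()), int(ys.max()) + 1
    if x1 - x0 < 3 or y1 - y0 < 3:
        return None

    hue = (motif["hue"] + rng.normal(0, 0.02)) % 1.0
    sat = np.clip(motif["sat"] + rng.normal(0, 0.08), 0.3, 1.0)
    val = rng.uniform(0.55, 0.95)
    rgb = np.array(colorsys.hsv_to_rgb(hue, sat, val)) * 255.0

    patch = np.ones((y1 - y0, x1 - x0), dtype=np.float64)
    if motif["tex"] == "speckle":
        patch *= 0.75 + 0.5 * rng.random(patch.shape)
    elif motif["tex"] == "stripes":
        xg, yg = np.meshgrid(np.arange(x1 - x0), np.arange(y1 - y0))
        phase = (xg * math.cos(rot) + yg * math.sin(rot)) / max(2.0, radius / 3.0)
        patch *= 0.8 + 0.25 * np.sin(2 * np.pi * phase)
    sub = mask[y0:y1, x0:x1]
    colored = rgb[None, None, :] * patch[:, :, None]
    region = img[y0:y1, x0:x1]
    region[sub] = np.clip(colored, 0, 255)[sub]
    return BoundingBox(float(x0), float(y0), float(x1), float(y1), class_id)


def generate_dataset(config: SceneConfig, n_images: int) -> list[AnnotatedImage]:
    """Generate ``n_images`` annotated scenes.

    Every image carries at least one box; per-class instance counts follow
    ``config.class_weights`` in expectation; output is deterministic given
    the config (including its seed).
    """
    if n_images < 1:
        raise SceneConfigError("n_images must be >= 1")
    rng = np.random.default_rng(config.seed)
    weights = config.weights()
    out: list[AnnotatedImage] = []
    for image_id in range(1, n_images + 1):
        img = _background(config, rng)
        n_boxes = config.box_count_law.sample(rng)
        annotations: list[BoundingBox] = []
        attempts = 0
        while len(annotations) < n_boxes and attempts < n_boxes * 4 + 8:
            attempts += 1
            class_id = int(rng.choice(config.num_classes, p=weights))
            box = _render_object(img, class_id, config, rng)
            if box is not None:
                annotations.append(box.clip(*config.image_size))
        if not annotations:  # pragma: no cover - shapes essentially never fail
            raise SceneConfigError("failed to place any object")
        out.append(
            AnnotatedImage(image_id, img.astype(np.uint8), annotations)
        )
    return out


# ---------------------------------------------------------------------------
# Splits and label fractions


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/val/test id lists covering the full dataset."""

    train_ids: tuple[int, ...]
    val_ids: tuple[int, ...]
    test_ids: tuple[int, ...]


@dataclass(frozen=True)
class LabeledPartition:
    """Labeled/unlabeled partition of the training ids at fraction ``p``."""

    labeled_ids: tuple[int, ...]
    unlabeled_ids: tuple[int, ...]
    fraction: float


def split_dataset(
    ids: list[int] | tuple[int, ...],
    ratios: tuple[float, float, float] = (0.65, 0.20, 0.15),
    seed: int = 0,
) -> DatasetSplit:
    """Random train/val/test split.

    Sizes use ceil on the val and test shares with the remainder assigned
    to train: ``|test| = ceil(r_test * n)``, ``|val| = ceil(r_val * n)``,
    ``|train| = n - |val| - |test|`` — the convention that yields
    (550, 170, 128) for n=848 and (3670, 1130, 848) for n=5648 at the
    65/20/15 ratios.
    """
    n = len(ids)
    if n < 3:
        raise SplitError(f"need at least 3 ids to split, got {n}")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise SplitError(f"ratios {ratios} must sum to 1")
    n_test = math.ceil(ratios[2] * n)
    n_val = math.ceil(ratios[1] * n)
    n_train = n - n_val - n_test
    if n_train < 1:
        raise SplitError("ratios leave no training images")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(n)]
    return DatasetSplit(
        train_ids=tuple(order[:n_train]),
        val_ids=tuple(order[n_train : n_train + n_val]),
        test_ids=tuple(order[n_train + n_val :]),
    )


def subsample_labeled(
    train_ids: list[int] | tuple[int, ...], p: float, seed: int = 0
) -> LabeledPartition:
    """Mark a fraction ``p`` (percent) of the training ids as labeled.

    ``|labeled| = ceil(p/100 * n)`` so any positive fraction keeps at least
    one labeled image.  A single seed-determined ordering is shared across
    fractions, so the labeled set is nested: labeled(p1) ⊆ labeled(p2)
    whenever p1 <= p2.
    """
    if not (0.0 < p <= 100.0):
        raise ValueError(f"label fraction p={p} outside (0, 100]")
    n = len(train_ids)
    n_labeled = math.ceil(p / 100.0 * n)
    rng = np.random.default_rng(seed)
    order = [train_ids[i] for i in rng.permutation(n)]
    return LabeledPartition(
        labeled_ids=tuple(order[:n_labeled]),
        unlabeled_ids=tuple(order[n_labeled:]),
        fraction=float(p),
    )


# ---------------------------------------------------------------------------
# COCO-dialect I/O


def write_coco(
    dataset: list[AnnotatedImage],
    json_path: str | Path,
    images_dir: str | Path | None = None,
    class_names: tuple[str, ...] | None = None,
) -> None:
    """Write the dataset as COCO-dialect JSON plus PNG image files.

    Boxes are serialized as ``[x, y, width, height]``; category ids are
    1-based in the file.  PNGs go to ``images_dir`` (default: an ``images``
    directory next to the JSON).
    """
    json_path = Path(json_path)
    if images_dir is None:
        images_dir = json_path.parent / "images"
    images_dir = Path(images_dir)
    images_dir.mkdir(parents=True, exist_ok=True)

    max_cls = max(
        (b.class_id for im in dataset for b in im.annotations), default=-1
    )
    if class_names is None:
        class_names = tuple(f"class_{i}" for i in range(max_cls + 1))
    images, annotations = [], []
    ann_id = 1
    for im in dataset:
        im.validate()
        fname = f"img_{im.image_id:06d}.png"
        Image.fromarray(im.pixels).save(images_dir / fname)
        images.append(
            {
                "id": im.image_id,
                "file_name": fname,
                "width": im.width,
                "height": im.height,
            }
        )
        for b in im.annotations:
            x, y, w, h = b.as_xywh()
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": im.image_id,
                    "category_id": b.class_id + 1,
                    "bbox": [round(v, 3) for v in (x, y, w, h)],
                    "area": round(w * h, 3),
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    payload = {
        "images": images,
        "annotations": annotations,
        "categories": [
            {"id": i + 1, "name": name} for i, name in enumerate(class_names)
        ],
    }
    json_path.write_text(json.dumps(payload))


def read_coco(
    json_path: str | Path, images_dir: str | Path | None = None
) -> list[AnnotatedImage]:
    """Read a COCO-dialect JSON (and its PNGs) back into memory.

    Raises :class:`CocoFormatError` naming the offending record on
    malformed input (missing tables, nonpositive box sizes, out-of-bounds
    boxes).
    """
    json_path = Path(json_path)
    if images_dir is None:
        images_dir = json_path.parent / "images"
    images_dir = Path(images_dir)
    try:
        payload = json.loads(json_path.read_text())
    except json.JSONDecodeError as exc:
        raise CocoFormatError(f"malformed JSON in {json_path}: {exc}") from exc
    for key in ("images", "annotations", "categories"):
        if key not in payload:
            raise CocoFormatError(f"missing top-level table {key!r}")
    cat_ids = {c["id"] for c in payload["categories"]}
    by_image: dict[int, list[BoundingBox]] = {}
    sizes: dict[int, tuple[int, int]] = {}
    files: dict[int, str] = {}
    for rec in payload["images"]:
        sizes[rec["id"]] = (rec["width"], rec["height"])
        files[rec["id"]] = rec["file_name"]
        by_image[rec["id"]] = []
    for rec in payload["annotations"]:
        if rec["image_id"] not in sizes:
            raise CocoFormatError(
                f"annotation {rec.get('id')} references unknown image "
                f"{rec['image_id']}"
            )
        if rec["category_id"] not in cat_ids:
            raise CocoFormatError(
                f"annotation {rec.get('id')} has unknown category "
                f"{rec['category_id']}"
            )
        x, y, w, h = rec["bbox"]
        if w <= 0 or h <= 0:
            raise CocoFormatError(
                f"annotation {rec.get('id')} has nonpositive box size "
                f"({w}, {h})"
            )
        iw, ih = sizes[rec["image_id"]]
        if x < -1e-6 or y < -1e-6 or x + w > iw + 1e-6 or y + h > ih + 1e-6:
            raise CocoFormatError(
                f"annotation {rec.get('id')} out of image bounds"
            )
        by_image[rec["image_id"]].append(
            BoundingBox.from_xywh(x, y, w, h, rec["category_id"] - 1)
        )
    out = []
    for image_id in sorted(sizes):
        iw, ih = sizes[image_id]
        png = images_dir / files[image_id]
        if png.exists():
            pixels = np.asarray(Image.open(png).convert("RGB"), dtype=np.uint8)
        else:
            pixels = np.zeros((ih, iw, 3), dtype=np.uint8)
        out.append(AnnotatedImage(image_id, pixels, by_image[image_id]))
    return out
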