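"""Axis-aligned bounding boxes and vectorized box geometry.

Coordinates are continuous, 0-based, corner form ``(x_min, y_min, x_max,
y_max)``; area is ``(x_max - x_min) * (y_max - y_min)``.  The COCO
``[x, y, w, h]`` convention appears only at the file boundary
(:mod:`weedssl.scene_forge`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BoundingBox:
    """One annotated, pseudo-labeled or detected object box.

    Parameters
    ----------
    x_min, y_min, x_max, y_max
        Corner coordinates in pixels; ``x_max > x_min`` and ``y_max > y_min``.
    class_id
        Integer category index in ``[0, num_classes)``.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    class_id: int

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max})"
            )
        if self.class_id < 0:
            raise ValueError(f"negative class_id {self.class_id}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def diagonal(self) -> float:
        return float(np.hypot(self.width, self.height))

    def as_xywh(self) -> tuple[float, float, float, float]:
        """COCO-style ``[x, y, width, height]``."""
        return (self.x_min, self.y_min, self.width, self.height)

    @classmethod
    def from_xywh(
        cls, x: float, y: float, w: float, h: float, class_id: int
    ) -> "BoundingBox":
        return cls(x, y, x + w, y + h, class_id)

    def clip(self, width: float, height: float) -> "BoundingBox":
        """Clip to image bounds ``[0, width] x [0, height]``."""
        return BoundingBox(
            max(0.0, self.x_min),
            max(0.0, self.y_min),
            min(float(width), self.x_max),
            min(float(height), self.y_max),
            self.class_id,
        )

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.x_min, self.y_min, self.x_max, self.y_max], dtype=np.float64
        )


def boxes_to_array(boxes: list[BoundingBox]) -> np.ndarray:
    """Stack corner coordinates into an ``(n, 4)`` float array."""
    if not boxes:
        return np.zeros((0, 4), dtype=np.float64)
    return np.stack([b.as_array() for b in boxes])


def box_classes(boxes: list[BoundingBox]) -> np.ndarray:
    return np.array([b.class_id for b in boxes], dtype=np.int64)


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise intersection-over-union of two corner-form box arrays.

    Parameters
    ----------
    a : (m, 4) array
    b : (n, 4) array

    Returns
    -------
    (m, n) array of IoU values in ``[0, 1]``.
    """
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    ix1 = np.maximum(a[:, None, 0], b[None, :, 0])
    iy1 = np.maximum(a[:, None, 1], b[None, :, 1])
    ix2 = np.minimum(a[:, None, 2], b[None, :, 2])
    iy2 = np.minimum(a[:, None, 3], b[None, :, 3])
    iw = np.clip(ix2 - ix1, 0.0, None)
    ih = np.clip(iy2 - iy1, 0.0, None)
    inter = iw * ih
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out
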