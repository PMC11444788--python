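"""Boxes, centroids, IoU and non-maximum suppression.

Coordinate convention: continuous pixel coordinates with the origin at the
top-left corner of the frame, x increasing rightward and y increasing
downward. Box area is ``(x_max - x_min) * (y_max - y_min)`` with no
one-pixel correction, so IoU is scale-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "Point2D",
    "BoundingBox",
    "Detection",
    "iou",
    "centroid",
    "non_max_suppression",
]


@dataclass(frozen=True)
class Point2D:
    """A continuous image-plane position in pixels."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"Point2D coordinates must be finite, got ({self.x}, {self.y})")


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in pixel coordinates, corners inclusive of edges."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if self.x_min > self.x_max or self.y_min > self.y_max:
            raise ValueError(
                f"Degenerate box ordering: ({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height


@dataclass(frozen=True)
class Detection:
    """A detector output: a box with a confidence score at a frame index."""

    frame: int
    box: BoundingBox
    confidence: float

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError(f"frame index must be >= 0, got {self.frame}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must lie in [0, 1], got {self.confidence}")


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes, in [0, 1].

    Two boxes whose union has zero area (both degenerate) give 0.
    """
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    union = a.area + b.area - inter
    if union <= 0:
        return 0.0
    return inter / union


def centroid(box: BoundingBox) -> Point2D:
    """Center of a box."""
    return Point2D((box.x_min + box.x_max) / 2.0, (box.y_min + box.y_max) / 2.0)


def non_max_suppression(dets: list[Detection], iou_threshold: float) -> list[Detection]:
    """Greedy NMS over one frame's detections.

    Detections are visited in descending confidence; each kept box suppresses
    any remaining box whose IoU with it strictly exceeds ``iou_threshold``.
    Ties in confidence are broken by smaller x_min, then smaller y_min, for
    determinism. The result is sorted by descending confidence.
    """
    if not dets:
        return []
    frames = {d.frame for d in dets}
    if len(frames) > 1:
        raise ValueError(f"NMS expects detections from a single frame, got frames {sorted(frames)}")
    ordered = sorted(dets, key=lambda d: (-d.confidence, d.box.x_min, d.box.y_min))
    kept: list[Detection] = []
    for cand in ordered:
        if all(iou(cand.box, k.box) <= iou_threshold for k in kept):
            kept.append(cand)
    return kept
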