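"""Per-frame detection: a built-in blob detector plus an external-file reader.

The blob detector targets infrared-style laboratory footage — small dark
bodies on a light background — by intensity thresholding and connected
components. It is deliberately detector-agnostic plumbing: users with a
trained neural detector supply its outputs through
:func:`read_external_detections` instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import measure

from .geometry import BoundingBox, Detection

__all__ = [
    "Frame",
    "DetectorConfig",
    "adjust_image_size",
    "detect_blobs",
    "filter_by_confidence",
    "read_external_detections",
]


@dataclass(frozen=True)
class Frame:
    """A grayscale video frame: intensities in [0, 255], row-major (y, x)."""

    index: int
    pixels: np.ndarray

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2 or self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError(f"frame pixels must be a non-empty 2-D array, got shape {self.pixels.shape}")


@dataclass(frozen=True)
class DetectorConfig:
    """Blob-detector settings.

    confidence_threshold and nms_iou default to 0.05 — deliberately lenient
    values suited to small, closely spaced targets. image_size is the
    requested maximum image dimension; it is snapped up to a multiple of the
    network stride (32) before use.
    """

    confidence_threshold: float = 0.05
    nms_iou: float = 0.05
    image_size: int = 1040
    intensity_threshold: float = 128.0
    min_area: float = 4.0
    max_area: float = 2000.0
    split_min_area: float | None = None
    split_min_separation: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise ValueError("confidence_threshold must lie in [0, 1]")
        if not 0.0 <= self.nms_iou <= 1.0:
            raise ValueError("nms_iou must lie in [0, 1]")
        if self.min_area > self.max_area:
            raise ValueError("min_area must not exceed max_area")


def adjust_image_size(requested: int, stride: int = 32) -> int:
    """Snap a requested image size up to the next multiple of the stride.

    Detector backbones require input dimensions divisible by their maximum
    stride; the nearest acceptable value is taken as the smallest multiple of
    ``stride`` that is >= ``requested`` (so 1040 with stride 32 becomes 1056).
    """
    if requested < 1 or stride < 1:
        raise ValueError(f"requested and stride must be positive, got {requested}, {stride}")
    return int(math.ceil(requested / stride) * stride)


def detect_blobs(frame: Frame, config: DetectorConfig = DetectorConfig()) -> list[Detection]:
    """Detect dark blobs in a light-background frame.

    Pixels darker than ``intensity_threshold`` are binarized, connected
    components outside the [min_area, max_area] pixel-count window are
    discarded, and each surviving component yields a tight bounding box.
    Confidence is the component's contrast against the background median,
    normalized to (0, 1].

    When ``config.split_min_area`` is set, a component at least that large
    is assumed to be two touching bodies (targets overlapping in the image)
    and is split into two detections by a deterministic 2-means clustering
    of its pixels — a learned detector typically still reports two boxes
    for partially overlapping targets, and the tracker relies on that.
    """
    img = np.asarray(frame.pixels, dtype=float)
    mask = img < config.intensity_threshold
    if not mask.any():
        return []
    background = float(np.median(img[~mask])) if (~mask).any() else 255.0
    if background <= 0:
        background = 255.0
    labels = measure.label(mask, connectivity=2)
    dets: list[Detection] = []
    for region in measure.regionprops(labels, intensity_image=img):
        if not (config.min_area <= region.area <= config.max_area):
            continue
        parts = [region.coords]
        if config.split_min_area is not None and region.area >= config.split_min_area:
            split = _split_two_means(region.coords, config.split_min_separation)
            if split is not None:
                parts = split
        boxes = []
        for coords in parts:
            r0, c0 = coords.min(axis=0)
            r1, c1 = coords.max(axis=0)
            box = BoundingBox(float(c0), float(r0), float(c1 + 1), float(r1 + 1))
            mean_int = float(img[coords[:, 0], coords[:, 1]].mean())
            contrast = (background - mean_int) / background
            conf = min(1.0, max(contrast, 1e-6))
            boxes.append((box, conf))
        if len(boxes) == 2:
            boxes = _disjoin_pair(boxes)
        for box, conf in boxes:
            dets.append(Detection(frame=frame.index, box=box, confidence=conf))
    return dets


def _disjoin_pair(boxes: list[tuple[BoundingBox, float]]) -> list[tuple[BoundingBox, float]]:
    """Trim two split-sibling boxes at the midline of their dominant
    separation axis so they do not overlap (and NMS cannot collapse them)."""
    (a, ca), (b, cb) = boxes
    acx, acy = (a.x_min + a.x_max) / 2, (a.y_min + a.y_max) / 2
    bcx, bcy = (b.x_min + b.x_max) / 2, (b.y_min + b.y_max) / 2
    if abs(acx - bcx) >= abs(acy - bcy):
        mid = (acx + bcx) / 2
        if acx > bcx:
            (a, ca), (b, cb) = (b, cb), (a, ca)
        a = BoundingBox(a.x_min, a.y_min, max(min(a.x_max, mid), a.x_min), a.y_max)
        b = BoundingBox(min(max(b.x_min, mid), b.x_max), b.y_min, b.x_max, b.y_max)
    else:
        mid = (acy + bcy) / 2
        if acy > bcy:
            (a, ca), (b, cb) = (b, cb), (a, ca)
        a = BoundingBox(a.x_min, a.y_min, a.x_max, max(min(a.y_max, mid), a.y_min))
        b = BoundingBox(b.x_min, min(max(b.y_min, mid), b.y_max), b.x_max, b.y_max)
    return [(a, ca), (b, cb)]


def _split_two_means(coords: np.ndarray, min_separation: float = 0.0) -> list[np.ndarray] | None:
    """Deterministic 2-means split of component pixel coordinates.

    Centers start at the extreme projections onto the principal axis; a
    handful of Lloyd iterations then separates the two lobes. Returns None
    if the split degenerates (one empty cluster) or the final cluster
    centroids are closer than ``min_separation`` — two bodies overlapping
    almost completely form a compact blob whose halves do not correspond to
    the individual bodies, and splitting such a blob invents positions.
    """
    pts = coords.astype(float)
    mean = pts.mean(axis=0)
    centered = pts - mean
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt[0]
    centers = np.stack([pts[int(np.argmin(proj))], pts[int(np.argmax(proj))]])
    assign = np.zeros(len(pts), dtype=int)
    for _ in range(8):
        d0 = np.linalg.norm(pts - centers[0], axis=1)
        d1 = np.linalg.norm(pts - centers[1], axis=1)
        new_assign = (d1 < d0).astype(int)
        if np.array_equal(new_assign, assign) and _ > 0:
            break
        assign = new_assign
        for k in (0, 1):
            sel = pts[assign == k]
            if len(sel) == 0:
                return None
            centers[k] = sel.mean(axis=0)
    a = coords[assign == 0]
    b = coords[assign == 1]
    if len(a) == 0 or len(b) == 0:
        return None
    if float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0))) < min_separation:
        return None
    return [a, b]


class AdaptiveBlobDetector:
    """Blob detector that learns the typical single-body pixel area online.

    Most components in a frame are single bodies, so the running median of
    component pixel areas estimates the single-body area; a component
    exceeding ``split_factor`` times that median is taken to be two touching
    bodies and split (see :func:`detect_blobs`). With ``split_factor`` set
    to None splitting is disabled and this reduces to :func:`detect_blobs`.
    """

    def __init__(self, config: DetectorConfig = DetectorConfig(), split_factor: float | None = 1.6,
                 min_samples: int = 20, max_samples: int = 500):
        self.config = config
        self.split_factor = split_factor
        self._areas: list[float] = []
        self._min_samples = min_samples
        self._max_samples = max_samples

    def __call__(self, frame: Frame) -> list[Detection]:
        import dataclasses

        cfg = self.config
        if self.split_factor is not None:
            if len(self._areas) < self._max_samples:
                img = np.asarray(frame.pixels, dtype=float)
                mask = img < cfg.intensity_threshold
                if mask.any():
                    counts = np.bincount(measure.label(mask, connectivity=2).ravel())[1:]
                    good = counts[(counts >= cfg.min_area) & (counts <= cfg.max_area)]
                    self._areas.extend(float(a) for a in good)
            if len(self._areas) >= self._min_samples:
                med = float(np.median(self._areas))
                cfg = dataclasses.replace(
                    cfg,
                    split_min_area=self.split_factor * med,
                    split_min_separation=1.5 * float(np.sqrt(med)),
                )
        return detect_blobs(frame, cfg)


def filter_by_confidence(dets: list[Detection], threshold: float) -> list[Detection]:
    """Keep detections whose confidence is >= threshold, order preserved.

    Scores exactly at the threshold are kept (only scores *below* it are
    filtered out).
    """
    return [d for d in dets if d.confidence >= threshold]


def read_external_detections(path: str | Path) -> dict[int, list[Detection]]:
    """Read a delimited detection file into a frame -> detections map.

    Format: one detection per row, comma-delimited,
    ``frame, x_min, y_min, width, height, confidence`` with 0-based frames
    (MOT-challenge-style ordering). A header row is permitted. Boxes are
    converted to corner form. Malformed rows and negative sizes raise with
    the offending line number.
    """
    result: dict[int, list[Detection]] = {}
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = [f.strip() for f in line.split(",")]
            if lineno == 1 and not _looks_numeric(fields[0]):
                continue  # header
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            try:
                frame = int(fields[0])
                x, y, w, h = (float(v) for v in fields[1:5])
                conf = float(fields[5])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {line!r}") from exc
            if w < 0 or h < 0:
                raise ValueError(f"{path}:{lineno}: negative box size (w={w}, h={h})")
            det = Detection(frame=frame, box=BoundingBox(x, y, x + w, y + h), confidence=conf)
            result.setdefault(frame, []).append(det)
    return result


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False
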