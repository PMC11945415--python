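"""Body/head mask extraction and detection-evaluation metrics.

Detection is behind the :class:`DetectorProvider` contract so the geometry
pipeline never depends on a particular detector: tests use
:class:`OracleDetector` (boxes from the synthetic renderer's ground truth)
and real annotations can be read with :class:`FileDetector`.  Boxes are
turned into masks by isolating the elevated (closer-to-camera) surface
inside each box relative to the surrounding bedding, followed by
morphological cleanup; the mat mask is the ring of valid-depth pixels
around the body.

Evaluation metrics are the standard detection ones: IoU between boxes, and
per-class average precision as the area under the all-point precision-
recall curve, averaged into mAP.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.morphology import closing, footprint_rectangle, opening

from .camera import CameraModel, DepthImage


class SegmentationError(RuntimeError):
    """Raised when no foreground surface can be isolated."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel rectangle with a class label and confidence."""

    label: str
    x: int          # min column
    y: int          # min row
    width: int
    height: int
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"box must have positive size, got {self.width}x{self.height}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")

    @property
    def area(self) -> int:
        return self.width * self.height

    def clipped(self, image_width: int, image_height: int) -> "BoundingBox":
        x0, y0 = max(self.x, 0), max(self.y, 0)
        x1 = min(self.x + self.width, image_width)
        y1 = min(self.y + self.height, image_height)
        if x1 <= x0 or y1 <= y0:
            raise ValueError("box lies entirely outside the image")
        return BoundingBox(self.label, x0, y0, x1 - x0, y1 - y0, self.confidence)

    def slices(self) -> tuple[slice, slice]:
        return slice(self.y, self.y + self.height), slice(self.x, self.x + self.width)


@dataclass
class SceneMasks:
    """Binary masks for the head, the body and the surrounding mat ring.

    Invariant: the mat mask excludes body and head; head and mat are
    disjoint by construction.
    """

    head_mask: np.ndarray
    body_mask: np.ndarray
    mat_mask: np.ndarray

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.head_mask, self.body_mask, self.mat_mask)}
        if len(shapes) != 1:
            raise ValueError("mask shapes differ")
        if np.any(self.mat_mask & (self.head_mask | self.body_mask)):
            raise ValueError("mat mask overlaps body/head")


@dataclass
class DetectionMetrics:
    per_class_ap: dict[str, float]
    map_score: float

    @property
    def n_classes(self) -> int:
        return len(self.per_class_ap)


# ---------------------------------------------------------------------------
# detector providers

class DetectorProvider:
    """Contract: return head/body boxes for a scene's depth image."""

    def detect(self, depth: DepthImage) -> list[BoundingBox]:  # pragma: no cover
        raise NotImplementedError


class OracleDetector(DetectorProvider):
    """Serves the ground-truth boxes attached to a synthetic scene."""

    def __init__(self, boxes: list[BoundingBox]):
        self._boxes = list(boxes)

    def detect(self, depth: DepthImage) -> list[BoundingBox]:
        return list(self._boxes)


class FileDetector(DetectorProvider):
    """Reads per-image annotations: whitespace-separated
    ``label x y width height [confidence]`` lines, or a JSON list of box
    objects with those keys."""

    def __init__(self, path):
        self._boxes = load_boxes(path)

    def detect(self, depth: DepthImage) -> list[BoundingBox]:
        return list(self._boxes)


def load_boxes(path) -> list[BoundingBox]:
    text = open(path).read()
    boxes: list[BoundingBox] = []
    if text.lstrip().startswith("["):
        for d in json.loads(text):
            boxes.append(BoundingBox(d["label"], int(d["x"]), int(d["y"]),
                                     int(d["width"]), int(d["height"]),
                                     float(d.get("confidence", 1.0))))
        return boxes
    for line in text.splitlines():
        parts = line.split()
        if not parts:
            continue
        conf = float(parts[5]) if len(parts) > 5 else 1.0
        boxes.append(BoundingBox(parts[0], int(parts[1]), int(parts[2]),
                                 int(parts[3]), int(parts[4]), conf))
    return boxes


def save_boxes(path, boxes: list[BoundingBox]) -> None:
    with open(path, "w") as fh:
        json.dump([{"label": b.label, "x": b.x, "y": b.y, "width": b.width,
                    "height": b.height, "confidence": b.confidence}
                   for b in boxes], fh, indent=2)


# ---------------------------------------------------------------------------
# masks

def clean_mask(mask: np.ndarray, kernel_size: int = 3) -> np.ndarray:
    """Morphological opening then closing with a square element.

    Removes isolated foreground pixels smaller than the element and refines
    object boundaries.  Idempotent on its own output.
    """
    if kernel_size < 3 or kernel_size % 2 == 0:
        raise ValueError(f"kernel size must be odd and >= 3, got {kernel_size}")
    mask = np.asarray(mask, dtype=bool)
    footprint = footprint_rectangle((kernel_size, kernel_size))
    return closing(opening(mask, footprint), footprint).astype(bool)


def _elevated_foreground(depth: DepthImage, box: BoundingBox,
                         min_elevation_mm: float) -> np.ndarray:
    """Pixels inside the box that stand proud of the local background.

    The background depth is the median depth of the box's surrounding
    frame; foreground pixels are at least ``min_elevation_mm`` closer to
    the camera.
    """
    h, w = depth.shape
    rs, cs = box.slices()
    inner = depth.values[rs, cs]
    inner_valid = inner != depth.missing_value

    pad = max(box.width, box.height) // 4 + 1
    r0, r1 = max(box.y - pad, 0), min(box.y + box.height + pad, h)
    c0, c1 = max(box.x - pad, 0), min(box.x + box.width + pad, w)
    frame = depth.values[r0:r1, c0:c1].copy()
    frame[(box.y - r0):(box.y - r0 + box.height),
          (box.x - c0):(box.x - c0 + box.width)] = depth.missing_value
    frame_vals = frame[frame != depth.missing_value]
    if frame_vals.size == 0:
        raise SegmentationError("no valid background depth around the box")
    background = float(np.median(frame_vals))

    fg = inner_valid & (inner < background - min_elevation_mm)
    mask = np.zeros(depth.shape, dtype=bool)
    mask[rs, cs] = fg
    return mask


def masks_from_boxes(depth: DepthImage, boxes: list[BoundingBox], *,
                     refine: bool = False, kernel_size: int = 3,
                     min_elevation_mm: float = 10.0,
                     mat_ring_px: int = 40) -> SceneMasks:
    """Build head/body/mat masks from detector boxes.

    Foreground inside each box is the surface elevated above the local
    bedding depth; with ``refine`` the elevation threshold is re-derived
    from the box's own depth histogram (midpoint between the foreground
    and background modes) instead of the fixed ``min_elevation_mm``.
    The mat mask is a ``mat_ring_px``-pixel dilation ring around the body
    (plus head), restricted to valid-depth pixels.
    """
    h, w = depth.shape
    by_label: dict[str, np.ndarray] = {}
    for box in boxes:
        box = box.clipped(w, h)
        if refine:
            rs, cs = box.slices()
            inner = depth.values[rs, cs]
            vals = inner[inner != depth.missing_value]
            if vals.size < 10:
                raise SegmentationError(f"box for '{box.label}' has almost no valid depth")
            # Split depths at the midpoint between the near (object) and far
            # (bedding) quartiles -- a box-seeded two-level refinement.
            near, far = np.percentile(vals, [10, 90])
            if far - near < 5.0:
                raise SegmentationError(
                    f"box for '{box.label}' contains no elevated surface")
            threshold = (near + far) / 2.0
            fg = (inner != depth.missing_value) & (inner < threshold)
            mask = np.zeros(depth.shape, dtype=bool)
            mask[rs, cs] = fg
        else:
            mask = _elevated_foreground(depth, box, min_elevation_mm)
        mask = clean_mask(mask, kernel_size)
        if not mask.any():
            raise SegmentationError(f"empty foreground for '{box.label}' after refinement")
        by_label[box.label] = by_label.get(box.label, np.zeros(depth.shape, bool)) | mask

    head = by_label.get("head", np.zeros(depth.shape, bool))
    body = by_label.get("body", np.zeros(depth.shape, bool))

    subject = body | head
    # ring = Euclidean-distance dilation of the subject by mat_ring_px
    dist = distance_transform_edt(~subject, sampling=None) if subject.any() else None
    if dist is None:
        raise SegmentationError("no subject pixels; cannot build a mat ring")
    ring = dist <= mat_ring_px
    mat = ring & ~subject & depth.valid_mask
    return SceneMasks(head_mask=head, body_mask=body, mat_mask=mat)


# ---------------------------------------------------------------------------
# metrics

def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes, in [0, 1]."""
    x0 = max(a.x, b.x)
    y0 = max(a.y, b.y)
    x1 = min(a.x + a.width, b.x + b.width)
    y1 = min(a.y + a.height, b.y + b.height)
    if x1 <= x0 or y1 <= y0:
        return 0.0
    overlap = (x1 - x0) * (y1 - y0)
    union = a.area + b.area - overlap
    return overlap / union


def _average_precision(predictions: list[BoundingBox],
                       truths: list[BoundingBox], iou_threshold: float) -> float:
    """All-point (continuous-envelope) AP with greedy confidence-ranked
    matching; each ground-truth box matches at most once."""
    n_truth = len(truths)
    if not predictions:
        return 0.0
    order = sorted(range(len(predictions)),
                   key=lambda i: -predictions[i].confidence)
    matched = [False] * n_truth
    tp = np.zeros(len(predictions))
    for rank, i in enumerate(order):
        best_iou, best_j = 0.0, -1
        for j, t in enumerate(truths):
            if matched[j]:
                continue
            v = iou(predictions[i], t)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[best_j] = True
            tp[rank] = 1.0
    cum_tp = np.cumsum(tp)
    precision = cum_tp / np.arange(1, len(tp) + 1)
    recall = cum_tp / n_truth
    # precision envelope, then area under PR via recall steps
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for p, r in zip(envelope, recall):
        if r > prev_r:
            ap += (r - prev_r) * p
            prev_r = r
    return float(ap)


def mean_average_precision(predictions: dict[str, list[BoundingBox]],
                           ground_truth: dict[str, list[BoundingBox]],
                           iou_threshold: float = 0.5) -> DetectionMetrics:
    """Per-class AP (area under the all-point precision-recall curve) and
    their mean.  Classes without ground truth are excluded with a warning."""
    if not (0.0 < iou_threshold < 1.0):
        raise ValueError(f"IoU threshold must be in (0, 1), got {iou_threshold}")
    per_class: dict[str, float] = {}
    for label in sorted(set(predictions) | set(ground_truth)):
        truths = ground_truth.get(label, [])
        if not truths:
            warnings.warn(f"no ground truth for class '{label}'; AP undefined, excluded")
            continue
        per_class[label] = _average_precision(predictions.get(label, []),
                                              truths, iou_threshold)
    if not per_class:
        raise ValueError("no class has ground truth; mAP undefined")
    return DetectionMetrics(per_class_ap=per_class,
                            map_score=float(np.mean(list(per_class.values()))))
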