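"""Detection-side geometry.

The detector contributes three anatomical landmarks (the apex and the two
mitral-annulus corners, here called ``top``, ``lower_left`` and
``lower_right``) and the LV region box.  This module holds the math that
surrounds those detections: YOLO-style bounding-box decoding from grid
offsets and anchor priors, IOU, anchor clustering with the 1-IOU metric,
conversion of raw detections into the constraint triplet the contour
stage consumes, and the LV crop with its coordinate round trip.

Network training and inference are deliberately absent: detections enter
through a small JSON contract (see :mod:`lvseg.io`) or from phantom
ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import GeometryError, MissingConstraintError, ValidationError
from .frame import UltrasoundFrame

#: The four detection classes: the LV region and the three constraint points.
CONSTRAINT_CLASSES = ("top", "lower_left", "lower_right")
ALL_CLASSES = ("LV",) + CONSTRAINT_CLASSES


@dataclass
class Detection:
    """One scored, classed axis-aligned bounding box.

    ``cx``/``cy`` are the center column/row in pixels (full-frame,
    0-based); ``w``/``h`` the box width and height in pixels.
    """

    cx: float
    cy: float
    w: float
    h: float
    conf: float = 1.0
    class_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValidationError(f"box size must be positive, got ({self.w}, {self.h})")
        if not 0.0 <= self.conf <= 1.0:
            raise ValidationError(f"confidence must be in [0, 1], got {self.conf}")
        if self.class_id is not None and self.class_id not in ALL_CLASSES:
            raise ValidationError(f"unknown class {self.class_id!r}")

    @property
    def x0(self) -> float:
        return self.cx - self.w / 2.0

    @property
    def y0(self) -> float:
        return self.cy - self.h / 2.0

    @property
    def x1(self) -> float:
        return self.cx + self.w / 2.0

    @property
    def y1(self) -> float:
        return self.cy + self.h / 2.0


@dataclass
class AnchorBox:
    """A prior box size (width, height) in pixels."""

    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValidationError("anchor dimensions must be positive")

    @property
    def area(self) -> float:
        return self.width * self.height


@dataclass
class GridSpec:
    """One detection head's grid: S x S cells over a square image."""

    grid_size: int
    cell_origin: Tuple[int, int]  # (C_x, C_y) in grid units
    image_size: int

    def __post_init__(self) -> None:
        if self.grid_size not in (13, 26, 52):
            raise ValidationError(f"grid_size must be one of 13/26/52, got {self.grid_size}")
        if self.image_size % self.grid_size != 0:
            raise ValidationError(
                f"grid size {self.grid_size} does not divide image size {self.image_size}"
            )

    @property
    def cell_pixels(self) -> float:
        return self.image_size / self.grid_size


@dataclass
class ConstraintTriplet:
    """The three landmark points, in full-frame (row, col) pixels."""

    apex: Tuple[float, float]
    lower_left: Tuple[float, float]
    lower_right: Tuple[float, float]

    def __post_init__(self) -> None:
        ar = self.apex[0]
        if not (ar < self.lower_left[0] and ar < self.lower_right[0]):
            raise GeometryError(
                "apex row must be above both bottom rows: "
                f"apex={self.apex}, lower_left={self.lower_left}, "
                f"lower_right={self.lower_right}"
            )
        if not self.lower_left[1] < self.lower_right[1]:
            raise GeometryError(
                "lower_left column must be left of lower_right column: "
                f"{self.lower_left[1]} vs {self.lower_right[1]}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.apex, self.lower_left, self.lower_right], dtype=float)


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def decode_box(
    t: Sequence[float], anchor: AnchorBox, grid: GridSpec
) -> Detection:
    """Decode raw network offsets into an absolute box.

    ``t = (t_x, t_y, t_w, t_h)`` are the regressed offsets; the center is
    ``sigma(t_x) + C_x`` grid units (then scaled to pixels by the cell
    size), and the size is the anchor scaled by ``exp(t_w)`` /
    ``exp(t_h)``.  The sigmoid keeps the decoded center inside its grid
    cell.
    """
    tx, ty, tw, th = (float(v) for v in t)
    cx_grid = _sigmoid(tx) + grid.cell_origin[0]
    cy_grid = _sigmoid(ty) + grid.cell_origin[1]
    scale = grid.cell_pixels
    return Detection(
        cx=cx_grid * scale,
        cy=cy_grid * scale,
        w=anchor.width * math.exp(tw),
        h=anchor.height * math.exp(th),
    )


def iou(box_a: Detection, box_b: Detection) -> float:
    """Intersection-over-union of two axis-aligned boxes (continuous)."""
    ix = max(0.0, min(box_a.x1, box_b.x1) - max(box_a.x0, box_b.x0))
    iy = max(0.0, min(box_a.y1, box_b.y1) - max(box_a.y0, box_b.y0))
    inter = ix * iy
    union = box_a.w * box_a.h + box_b.w * box_b.h - inter
    return inter / union if union > 0 else 0.0


def _iou_wh(w1: np.ndarray, h1: np.ndarray, w2: float, h2: float) -> np.ndarray:
    """IOU of origin-centered boxes given only widths/heights (vectorized)."""
    inter = np.minimum(w1, w2) * np.minimum(h1, h2)
    union = w1 * h1 + w2 * h2 - inter
    return inter / union


def cluster_anchors(
    boxes: Sequence[Tuple[float, float]], k: int, seed: int = 0
) -> List[AnchorBox]:
    """Cluster training-box sizes into ``k`` anchor priors.

    K-means with the YOLO distance ``d(box, anchor) = 1 - IOU(box,
    anchor)`` where both boxes are centered at the origin; the centroid
    update is the per-cluster mean of ``(w, h)``.  Returns anchors sorted
    by area ascending.
    """
    wh = np.asarray(boxes, dtype=float)
    if wh.ndim != 2 or wh.shape[1] != 2:
        raise ValidationError("boxes must be a sequence of (w, h) pairs")
    if np.any(wh <= 0):
        raise ValidationError("all box dimensions must be positive")
    n = len(wh)
    if n < k:
        raise ValidationError(f"need at least k={k} boxes, got {n}")

    rng = np.random.default_rng(seed)
    centers = wh[rng.choice(n, size=k, replace=False)].copy()
    assign = np.zeros(n, dtype=int)
    for _ in range(300):
        dists = np.stack(
            [1.0 - _iou_wh(wh[:, 0], wh[:, 1], cw, ch) for cw, ch in centers],
            axis=1,
        )
        new_assign = np.argmin(dists, axis=1)
        for j in range(k):
            members = wh[new_assign == j]
            if len(members):
                centers[j] = members.mean(axis=0)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    anchors = [AnchorBox(float(w), float(h)) for w, h in centers]
    anchors.sort(key=lambda a: a.area)
    return anchors


def anchor_assignment_cost(
    boxes: Sequence[Tuple[float, float]], anchors: Sequence[AnchorBox]
) -> float:
    """Mean ``1 - IOU`` of each box to its best anchor (clustering objective)."""
    wh = np.asarray(boxes, dtype=float)
    dists = np.stack(
        [1.0 - _iou_wh(wh[:, 0], wh[:, 1], a.width, a.height) for a in anchors],
        axis=1,
    )
    return float(dists.min(axis=1).mean())


def constraints_from_detections(dets: Sequence[Detection]) -> ConstraintTriplet:
    """Reduce a detection list to the constraint triplet.

    For each constraint class the highest-confidence detection wins and
    its box center becomes the landmark point.
    """
    best = {}
    for d in dets:
        if d.class_id in CONSTRAINT_CLASSES:
            if d.class_id not in best or d.conf > best[d.class_id].conf:
                best[d.class_id] = d
    for cls in CONSTRAINT_CLASSES:
        if cls not in best:
            raise MissingConstraintError(f"no detection of class {cls!r}")
    point = lambda d: (d.cy, d.cx)  # noqa: E731  (row, col)
    return ConstraintTriplet(
        apex=point(best["top"]),
        lower_left=point(best["lower_left"]),
        lower_right=point(best["lower_right"]),
    )


def lv_box_from_detections(dets: Sequence[Detection]) -> Detection:
    """The highest-confidence LV-region detection."""
    lv = [d for d in dets if d.class_id == "LV"]
    if not lv:
        raise MissingConstraintError("no detection of class 'LV'")
    return max(lv, key=lambda d: d.conf)


def crop_lv(
    frame: UltrasoundFrame, lv_box: Detection, margin: int = 10
) -> Tuple[UltrasoundFrame, Tuple[int, int]]:
    """Crop the LV box (dilated by ``margin``) out of the frame.

    Returns ``(subframe, offset)`` where ``offset = (row0, col0)`` maps
    sub-frame coordinates back to full-frame coordinates; bounds are
    half-open and clamped to the frame.
    """
    h, w = frame.shape
    r0 = max(0, int(math.floor(lv_box.y0)) - margin)
    r1 = min(h, int(math.ceil(lv_box.y1)) + margin)
    c0 = max(0, int(math.floor(lv_box.x0)) - margin)
    c1 = min(w, int(math.ceil(lv_box.x1)) + margin)
    if r1 <= r0 or c1 <= c0:
        raise GeometryError("LV box does not intersect the frame")
    sub = frame.with_pixels(frame.pixels[r0:r1, c0:c1])
    return sub, (r0, c0)
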