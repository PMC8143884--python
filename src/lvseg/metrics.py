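"""Segmentation and detection evaluation metrics.

Region overlap is measured with the Dice coefficient
``2|S n G| / (|S| + |G|)``; contour agreement with the symmetric mean
absolute distance (MAD) and the Hausdorff distance (HD) over the sampled
contour vertices.  Detection quality is measured with greedy IOU
matching, precision/recall curves and average precision (area under the
interpolated precision envelope, i.e. the integral AP definition).

Distances are reported in pixels unless per-axis pixel spacing is
supplied, in which case coordinates are scaled to millimetres before the
distances are taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .errors import UndefinedMetricError, ValidationError
from .geometry import Detection, iou


@dataclass
class SegEvalReport:
    dice: float
    mad: float
    hausdorff: float
    units: str = "px"
    pixel_spacing: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.dice <= 1.0:
            raise ValidationError("dice out of [0, 1]")
        if self.mad > self.hausdorff + 1e-9:
            raise ValidationError("MAD cannot exceed the Hausdorff distance")

    def to_dict(self) -> Dict:
        return {
            "dice": self.dice,
            "mad": self.mad,
            "hd": self.hausdorff,
            "units": self.units,
        }


@dataclass
class DetEvalReport:
    per_class_ap: Dict[str, float]
    map: float
    curves: Dict[str, List[Tuple[float, float, float]]]  # (recall, precision, conf)
    iou_threshold: float = 0.5
    #: the IOU comparison is inclusive (a match requires IOU >= threshold)
    iou_inclusive: bool = True


# ---------------------------------------------------------------------------
# Segmentation metrics
# ---------------------------------------------------------------------------

def dice(mask_s: np.ndarray, mask_g: np.ndarray) -> float:
    """Dice overlap of two same-shape binary masks."""
    s = np.asarray(mask_s, dtype=bool)
    g = np.asarray(mask_g, dtype=bool)
    if s.shape != g.shape:
        raise ValidationError("masks must have the same shape")
    ns, ng = int(s.sum()), int(g.sum())
    if ns == 0 and ng == 0:
        raise UndefinedMetricError("Dice is undefined for two empty masks")
    inter = int((s & g).sum())
    return 2.0 * inter / (ns + ng)


def _scaled(points: np.ndarray, spacing: Optional[Tuple[float, float]]) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("point set must be (N, 2)")
    if pts.shape[0] == 0:
        raise UndefinedMetricError("empty point set")
    if spacing is not None:
        pts = pts * np.asarray(spacing, dtype=float)[None, :]
    return pts


def _directed_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    tree = cKDTree(b)
    d, _ = tree.query(a)
    return d


def mad(
    contour_a: np.ndarray,
    contour_b: np.ndarray,
    spacing: Optional[Tuple[float, float]] = None,
) -> float:
    """Symmetric mean absolute point-to-set distance between contours."""
    a = _scaled(contour_a, spacing)
    b = _scaled(contour_b, spacing)
    fwd = _directed_dists(a, b).mean()
    bwd = _directed_dists(b, a).mean()
    return 0.5 * (fwd + bwd)


def hausdorff(
    contour_a: np.ndarray,
    contour_b: np.ndarray,
    spacing: Optional[Tuple[float, float]] = None,
) -> float:
    """Symmetric Hausdorff (max-max point-to-set) distance."""
    a = _scaled(contour_a, spacing)
    b = _scaled(contour_b, spacing)
    return float(max(_directed_dists(a, b).max(), _directed_dists(b, a).max()))


def evaluate_segmentation(
    pred_contour: np.ndarray,
    truth_contour: np.ndarray,
    pred_mask: Optional[np.ndarray] = None,
    truth_mask: Optional[np.ndarray] = None,
    spacing: Optional[Tuple[float, float]] = None,
) -> SegEvalReport:
    """Bundle Dice (when masks are given), MAD and HD into one report."""
    d = dice(pred_mask, truth_mask) if pred_mask is not None and truth_mask is not None else float("nan")
    return SegEvalReport(
        dice=0.0 if np.isnan(d) else d,
        mad=mad(pred_contour, truth_contour, spacing),
        hausdorff=hausdorff(pred_contour, truth_contour, spacing),
        units="mm" if spacing is not None else "px",
        pixel_spacing=spacing,
    )


# ---------------------------------------------------------------------------
# Detection metrics
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    """Greedy confidence-ordered matching of one class's detections."""

    #: (confidence, is_true_positive) per detection, confidence descending
    flags: List[Tuple[float, bool]] = field(default_factory=list)
    n_truth: int = 0

    @property
    def tp(self) -> int:
        return sum(1 for _, t in self.flags if t)

    @property
    def fp(self) -> int:
        return sum(1 for _, t in self.flags if not t)

    @property
    def fn(self) -> int:
        return self.n_truth - self.tp


def match_detections(
    dets: Sequence[Detection],
    truths: Sequence[Detection],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedily match detections (one class) to ground-truth boxes.

    Detections are visited by descending confidence; each claims the
    unmatched truth with the highest IOU provided IOU >= threshold
    (inclusive).  Unclaimed detections are false positives, unclaimed
    truths false negatives.
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i].conf)
    taken = [False] * len(truths)
    flags: List[Tuple[float, bool]] = []
    for i in order:
        best_j, best_iou = -1, -1.0
        for j, t in enumerate(truths):
            if taken[j]:
                continue
            v = iou(dets[i], t)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_threshold:
            taken[best_j] = True
            flags.append((dets[i].conf, True))
        else:
            flags.append((dets[i].conf, False))
    return MatchResult(flags=flags, n_truth=len(truths))


def pr_curve(match: MatchResult) -> List[Tuple[float, float, float]]:
    """(recall, precision, confidence) at every distinct confidence cut."""
    if match.n_truth == 0:
        raise UndefinedMetricError("PR curve undefined with zero ground truths")
    if not match.flags:
        return [(0.0, 1.0, float("inf"))]
    flags = sorted(match.flags, key=lambda f: -f[0])
    points: List[Tuple[float, float, float]] = []
    tp = fp = 0
    for idx, (conf, is_tp) in enumerate(flags):
        if is_tp:
            tp += 1
        else:
            fp += 1
        # emit a point at each distinct threshold (last of a tie group)
        if idx + 1 < len(flags) and flags[idx + 1][0] == conf:
            continue
        points.append((tp / match.n_truth, tp / (tp + fp), conf))
    return points


def average_precision(curve: Sequence[Tuple[float, float, float]]) -> float:
    """Area under the precision envelope (all-point interpolation).

    Precision at each recall is replaced by the maximum precision at any
    recall >= it, then integrated over recall.
    """
    if not curve:
        return 0.0
    pts = np.asarray([(r, p) for r, p, *_ in curve], dtype=float)
    order = np.argsort(pts[:, 0], kind="stable")
    rec = pts[order, 0]
    prec = pts[order, 1]
    env = np.maximum.accumulate(prec[::-1])[::-1]
    ap = 0.0
    prev_r = 0.0
    for r, p in zip(rec, env):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def evaluate_detections(
    dets: Sequence[Detection],
    truths: Sequence[Detection],
    iou_threshold: float = 0.5,
) -> DetEvalReport:
    """Per-class AP and mAP over all classes present in the truth set."""
    classes = sorted({t.class_id for t in truths if t.class_id is not None})
    if not classes:
        raise UndefinedMetricError("no classed ground truths")
    per_class: Dict[str, float] = {}
    curves: Dict[str, List[Tuple[float, float, float]]] = {}
    for cls in classes:
        m = match_detections(
            [d for d in dets if d.class_id == cls],
            [t for t in truths if t.class_id == cls],
            iou_threshold,
        )
        curve = pr_curve(m)
        curves[cls] = curve
        per_class[cls] = average_precision(curve)
    return DetEvalReport(
        per_class_ap=per_class,
        map=float(np.mean(list(per_class.values()))),
        curves=curves,
        iou_threshold=iou_threshold,
    )
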