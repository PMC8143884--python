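"""Wall fitting and endocardial edge extraction.

Given the binary myocardium field and the three constraint points
(apex and the two mitral-annulus corners), this module:

1. samples candidate wall points — the endocardial (inner) edge of the
   myocardium on each side of the cavity midline;
2. fits each wall with a cubic polynomial, column as a function of row,
   by linear least squares (``X = (B^T B)^{-1} B^T L``), optionally with
   hard equality constraints forcing the curve through the apex and the
   side's bottom landmark (solved through a bordered KKT system);
3. builds a morphological cavity mask between the two fitted curves and
   uses it to suppress speckle islands in the binary field;
4. approaches the endocardial edge by ray casting from the cavity
   midline (horizontal rays along the walls, a radial fan near the
   apex), inserting the constraint points verbatim;
5. smooths the ordered contour with a cubic B-spline under chord-length
   parameterization.

The cubic is fitted on rows affinely rescaled to [-1, 1]; a raw cubic
Vandermonde on pixel rows is badly conditioned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import interpolate
from scipy.ndimage import binary_closing, distance_transform_cdt, label as cc_label

from .errors import (
    ConstraintConflictError,
    ExtractionFailureError,
    GeometryError,
    InsufficientSupportError,
    ValidationError,
)
from .frame import UltrasoundFrame
from .geometry import ConstraintTriplet
from .mrf import LabelField

logger = logging.getLogger(__name__)


@dataclass
class WallCurve:
    """One myocardial wall as a polynomial ``col = F(row)``.

    Coefficients are stored on the normalized row axis
    ``t = (row - row_mid) / row_half`` in ``numpy.polyval`` order
    (highest degree first); :meth:`__call__` evaluates in pixel
    coordinates.  Evaluation is only meaningful within ``row_range``.
    """

    coefficients: np.ndarray
    row_range: Tuple[float, float]
    row_mid: float
    row_half: float
    side: Optional[str] = None  # "left" | "right"
    residual_ss: float = 0.0

    def __post_init__(self) -> None:
        if self.row_range[0] >= self.row_range[1]:
            raise ValidationError(f"row_range must increase, got {self.row_range}")

    def __call__(self, rows: np.ndarray) -> np.ndarray:
        t = (np.asarray(rows, dtype=float) - self.row_mid) / self.row_half
        return np.polyval(self.coefficients, t)


@dataclass
class EndocardialContour:
    """Ordered open contour lower_left -> apex -> lower_right."""

    points: np.ndarray  # (N, 2) float, (row, col)
    closed: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValidationError("contour points must be an (N, 2) array")
        if len(self.points) < 3:
            raise ValidationError("contour needs at least 3 points")

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# Wall point sampling
# ---------------------------------------------------------------------------

def sample_wall_points(
    labels: LabelField, constraints: ConstraintTriplet
) -> Tuple[np.ndarray, np.ndarray]:
    """Endocardial-edge sample points for the left and right wall.

    The cavity is split along the line from the apex to the midpoint of
    the two bottom landmarks (a constant split column misassigns wall
    pixels near the apex, where the cavity is narrow and off-center).
    For every image row between the apex row and the lowest bottom row,
    the innermost myocardium pixel on each side of the split contributes
    one sample placed on the myocardium/cavity edge (half a pixel inside
    the innermost myocardium pixel); rows whose split pixel is itself
    myocardium (no clean left/right gap) and rows without myocardium on
    a side are skipped.
    """
    myo = labels.myocardium_mask
    h, w = myo.shape
    apex_r, apex_c = constraints.apex
    bottom_r = max(constraints.lower_left[0], constraints.lower_right[0])
    bottom_c = (constraints.lower_left[1] + constraints.lower_right[1]) / 2.0
    r_top = max(0, int(math.ceil(apex_r)))
    r_bot = min(h - 1, int(math.floor(bottom_r)))
    left_pts: List[Tuple[float, float]] = []
    right_pts: List[Tuple[float, float]] = []
    for r in range(r_top, r_bot + 1):
        frac = (r - apex_r) / (bottom_r - apex_r) if bottom_r > apex_r else 1.0
        split_idx = int(round(apex_c + frac * (bottom_c - apex_c)))
        split_idx = min(max(split_idx, 0), w - 1)
        row = myo[r]
        if row[split_idx]:
            continue  # split line is not inside the cavity gap at this row
        left_cols = np.nonzero(row[:split_idx])[0]
        if left_cols.size:
            left_pts.append((float(r), float(left_cols[-1]) + 0.5))
        right_cols = np.nonzero(row[split_idx:])[0]
        if right_cols.size:
            right_pts.append((float(r), float(right_cols[0] + split_idx) - 0.5))
    for name, pts in (("left", left_pts), ("right", right_pts)):
        if len(pts) < 5:  # degree 3 needs m+2 points for an overdetermined fit
            raise InsufficientSupportError(
                f"only {len(pts)} wall samples on the {name} side"
            )
    return np.array(left_pts), np.array(right_pts)


# ---------------------------------------------------------------------------
# Polynomial fitting
# ---------------------------------------------------------------------------

def _design(rows: np.ndarray, degree: int, mid: float, half: float) -> np.ndarray:
    t = (rows - mid) / half
    return np.vander(t, degree + 1)  # columns t^m ... t^0


def _row_transform(rows: np.ndarray) -> Tuple[float, float]:
    lo, hi = float(rows.min()), float(rows.max())
    mid = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo)
    if half <= 0:
        raise InsufficientSupportError("all sample rows are identical")
    return mid, half


def fit_wall(
    points: np.ndarray, degree: int = 3, side: Optional[str] = None
) -> WallCurve:
    """Unconstrained least-squares polynomial fit, col as function of row."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("points must be an (N, 2) array of (row, col)")
    rows, cols = pts[:, 0], pts[:, 1]
    if np.unique(rows).size < degree + 1:
        raise InsufficientSupportError(
            f"need {degree + 1} distinct rows, got {np.unique(rows).size}"
        )
    mid, half = _row_transform(rows)
    B = _design(rows, degree, mid, half)
    coef, *_ = np.linalg.lstsq(B, cols, rcond=None)
    resid = B @ coef - cols
    return WallCurve(
        coefficients=coef,
        row_range=(float(rows.min()), float(rows.max())),
        row_mid=mid,
        row_half=half,
        side=side,
        residual_ss=float(resid @ resid),
    )


def fit_wall_constrained(
    points: np.ndarray,
    constraint_points: np.ndarray,
    degree: int = 3,
    side: Optional[str] = None,
) -> WallCurve:
    """Least squares subject to the curve passing through given points.

    Minimizes ``||B X - L||^2`` subject to ``C X = d`` via the bordered
    (KKT) normal-equation system; the fitted curve satisfies each
    constraint to well below 1e-6 px.
    """
    pts = np.asarray(points, dtype=float)
    cons = np.asarray(constraint_points, dtype=float)
    if cons.ndim != 2 or cons.shape[1] != 2:
        raise ValidationError("constraint_points must be (K, 2) (row, col) pairs")
    rows, cols = pts[:, 0], pts[:, 1]
    if np.unique(rows).size < degree + 1:
        raise InsufficientSupportError(
            f"need {degree + 1} distinct rows, got {np.unique(rows).size}"
        )
    c_rows, c_cols = cons[:, 0], cons[:, 1]
    # identical constraint rows with different columns cannot both hold
    for i in range(len(cons)):
        for j in range(i + 1, len(cons)):
            if abs(c_rows[i] - c_rows[j]) < 1e-9 and abs(c_cols[i] - c_cols[j]) > 1e-9:
                raise ConstraintConflictError(
                    f"constraints at the same row {c_rows[i]} demand different columns"
                )
    all_rows = np.concatenate([rows, c_rows])
    mid, half = _row_transform(all_rows)
    B = _design(rows, degree, mid, half)
    C = _design(c_rows, degree, mid, half)
    d = c_cols
    p = degree + 1
    k = len(cons)
    kkt = np.zeros((p + k, p + k))
    kkt[:p, :p] = 2.0 * B.T @ B
    kkt[:p, p:] = C.T
    kkt[p:, :p] = C
    rhs = np.concatenate([2.0 * B.T @ cols, d])
    try:
        sol = np.linalg.solve(kkt, rhs)
    except np.linalg.LinAlgError as exc:
        raise ConstraintConflictError(f"singular constrained system: {exc}") from exc
    coef = sol[:p]
    err = np.abs(C @ coef - d).max()
    if err > 1e-6:
        raise ConstraintConflictError(
            f"constraints not satisfiable (max violation {err:.2e} px)"
        )
    resid = B @ coef - cols
    lo = float(min(rows.min(), c_rows.min()))
    hi = float(max(rows.max(), c_rows.max()))
    return WallCurve(
        coefficients=coef,
        row_range=(lo, hi),
        row_mid=mid,
        row_half=half,
        side=side,
        residual_ss=float(resid @ resid),
    )


# ---------------------------------------------------------------------------
# Morphological cavity mask
# ---------------------------------------------------------------------------

def build_cavity_mask(
    left: WallCurve,
    right: WallCurve,
    constraints: ConstraintTriplet,
    shape: Tuple[int, int],
) -> np.ndarray:
    """Pixels between the two fitted walls, apex row to bottom row.

    Pixel ``(r, c)`` belongs iff ``apex_row <= r <= max bottom row`` and
    ``F_left(r) <= c <= F_right(r)`` (inclusive); the raster is then
    morphologically closed with a 3x3 square to seal gaps.
    """
    h, w = shape
    r0 = max(0, int(math.ceil(constraints.apex[0] - 1e-9)))
    r1 = min(
        h - 1,
        int(math.floor(max(constraints.lower_left[0], constraints.lower_right[0]) + 1e-9)),
    )
    mask = np.zeros(shape, dtype=bool)
    for r in range(r0, r1 + 1):
        lc = float(left(r))
        rc = float(right(r))
        if lc > rc + 1e-9:
            raise GeometryError(f"wall curves cross at row {r} ({lc:.2f} > {rc:.2f})")
        c0 = max(0, int(math.ceil(lc - 1e-9)))
        c1 = min(w - 1, int(math.floor(rc + 1e-9)))
        if c1 >= c0:
            mask[r, c0 : c1 + 1] = True
    return binary_closing(mask, structure=np.ones((3, 3), dtype=bool))


def mask_binary(
    labels: LabelField,
    cavity_mask: np.ndarray,
    dilation: int = 5,
    min_component: int = 20,
) -> LabelField:
    """Suppress myocardium labels far from the cavity and speckle islands.

    A myocardium component survives only if it touches the cavity mask
    dilated by ``dilation`` pixels (square structuring element) — the
    wall band itself always does — and is not an isolated island of
    fewer than ``min_component`` pixels lying entirely inside the
    cavity (speckle).
    """
    if labels.labels.shape != cavity_mask.shape:
        raise ValidationError("label field and cavity mask shapes differ")
    myo = labels.myocardium_mask
    # square-SE dilation by `dilation` px == chessboard distance <= dilation
    if cavity_mask.any():
        region = distance_transform_cdt(~cavity_mask, metric="chessboard") <= dilation
    else:
        region = cavity_mask
    kept = myo.copy()
    comp, n = cc_label(myo, structure=np.ones((3, 3), dtype=int))
    for i in range(1, n + 1):
        members = comp == i
        if not (members & region).any():
            kept[members] = False  # clutter far from the cavity
        elif members.sum() < min_component and bool((members <= cavity_mask).all()):
            kept[members] = False  # speckle island inside the cavity
    out = np.where(kept, labels.myocardium_label, 1 - labels.myocardium_label)
    return LabelField(labels=out.astype(labels.labels.dtype), myocardium_label=labels.myocardium_label)


def remove_small_components(labels: LabelField, min_component: int = 20) -> LabelField:
    """Drop 8-connected myocardium components below ``min_component`` px.

    Used before wall fitting so isolated speckle islands in the cavity
    cannot masquerade as the innermost wall pixel.
    """
    myo = labels.myocardium_mask
    comp, n = cc_label(myo, structure=np.ones((3, 3), dtype=int))
    if n:
        sizes = np.bincount(comp.ravel())
        small = np.zeros(n + 1, dtype=bool)
        small[1:] = sizes[1:] < min_component
        myo = myo & ~small[comp]
    out = np.where(myo, labels.myocardium_label, 1 - labels.myocardium_label)
    return LabelField(labels=out.astype(labels.labels.dtype), myocardium_label=labels.myocardium_label)


# ---------------------------------------------------------------------------
# Edge approach
# ---------------------------------------------------------------------------

def _cavity_midline(cavity_mask: np.ndarray) -> Dict[int, float]:
    mid: Dict[int, float] = {}
    rows = np.nonzero(cavity_mask.any(axis=1))[0]
    for r in rows:
        cols = np.nonzero(cavity_mask[r])[0]
        mid[int(r)] = 0.5 * (cols[0] + cols[-1])
    return mid


def approach_endocardium(
    labels_masked: LabelField,
    constraints: ConstraintTriplet,
    cavity_mask: np.ndarray,
) -> EndocardialContour:
    """Ray-cast from the cavity midline to the inner myocardial edge.

    For each row from the apex down to the bottom landmarks a horizontal
    ray runs from the midline outward until the first myocardium pixel;
    the contour point is the last non-myocardium position (half a pixel
    short of the hit).  Rows above the first row where both horizontal
    rays hit are covered by a radial fan of rays aimed around the apex.
    The three constraint points are inserted verbatim as the first, apex
    and last vertices.
    """
    myo = labels_masked.myocardium_mask
    h, w = myo.shape
    midline = _cavity_midline(cavity_mask)
    if not midline:
        raise ExtractionFailureError("empty cavity mask")

    bl_row = int(math.floor(constraints.lower_left[0]))
    br_row = int(math.floor(constraints.lower_right[0]))
    rows_avail = sorted(midline)
    left_pts: List[Tuple[float, float]] = []
    right_pts: List[Tuple[float, float]] = []
    attempted = 0
    skipped = 0
    first_both: Optional[int] = None
    for r in rows_avail:
        if r > max(bl_row, br_row):
            break
        start = int(round(midline[r]))
        start = min(max(start, 0), w - 1)
        attempted += 1
        hit_l = hit_r = None
        if r <= bl_row:
            row_left = myo[r, : start + 1]
            nz = np.nonzero(row_left)[0]
            if nz.size:
                hit_l = int(nz[-1])
        if r <= br_row:
            row_right = myo[r, start:]
            nz = np.nonzero(row_right)[0]
            if nz.size:
                hit_r = int(nz[0] + start)
        if hit_l is None and hit_r is None:
            skipped += 1
            logger.debug("edge approach: no myocardium hit on row %d", r)
            continue
        if hit_l is not None and hit_r is not None and first_both is None:
            first_both = r
        if hit_l is not None and first_both is not None:
            left_pts.append((float(r), hit_l + 0.5))
        if hit_r is not None and first_both is not None:
            right_pts.append((float(r), hit_r - 0.5))
    if attempted and skipped / attempted > 0.5:
        raise ExtractionFailureError(
            f"edge approach failed on {skipped}/{attempted} rows"
        )
    if first_both is None:
        raise ExtractionFailureError("horizontal rays never hit both walls")

    # radial fan toward the apex for rows above first_both
    fan_left: List[Tuple[float, float]] = []
    fan_right: List[Tuple[float, float]] = []
    apex_r, apex_c = constraints.apex
    center = np.array([float(first_both), midline[first_both]])
    for theta in np.linspace(165.0, 15.0, 11):
        rad = math.radians(theta)
        d = np.array([-math.sin(rad), math.cos(rad)])  # up and sideways
        pos = center.copy()
        hit = None
        for _ in range(4 * max(h, w)):
            pos = pos + 0.5 * d
            ri, ci = int(round(pos[0])), int(round(pos[1]))
            if not (0 <= ri < h and 0 <= ci < w):
                break
            if myo[ri, ci]:
                hit = pos - 0.5 * d
                break
        if hit is None:
            continue
        if hit[0] >= first_both:  # fan only contributes above the row band
            continue
        if hit[1] < apex_c:
            fan_left.append((float(hit[0]), float(hit[1])))
        else:
            fan_right.append((float(hit[0]), float(hit[1])))

    # order: lower_left -> up the left wall -> fan -> apex -> fan -> down right
    left_pts.sort(key=lambda p: -p[0])
    fan_left.sort(key=lambda p: -p[0])  # ascending toward the apex
    fan_right.sort(key=lambda p: p[0])
    right_pts.sort(key=lambda p: p[0])
    seq: List[Tuple[float, float]] = [tuple(constraints.lower_left)]
    seq += left_pts + fan_left
    seq.append(tuple(constraints.apex))
    seq += fan_right + right_pts
    seq.append(tuple(constraints.lower_right))
    # drop consecutive duplicates
    pts: List[Tuple[float, float]] = []
    for p in seq:
        if not pts or (abs(p[0] - pts[-1][0]) > 1e-9 or abs(p[1] - pts[-1][1]) > 1e-9):
            pts.append(p)
    if len(pts) < 3:
        raise ExtractionFailureError("too few contour vertices extracted")
    return EndocardialContour(points=np.array(pts))


# ---------------------------------------------------------------------------
# B-spline smoothing
# ---------------------------------------------------------------------------

def chord_parameters(points: np.ndarray) -> np.ndarray:
    """Normalized cumulative chord-length parameters of an ordered polyline."""
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(seg)])
    if u[-1] <= 0:
        raise ValidationError("contour has zero length")
    return u / u[-1]


def smooth_bspline(
    contour: EndocardialContour,
    smoothing: Optional[float] = None,
    n_out: int = 100,
    params: Optional[np.ndarray] = None,
) -> EndocardialContour:
    """Cubic B-spline smoothing under chord-length parameterization.

    ``smoothing`` is the FITPACK residual budget; ``None`` uses the
    number of input points (a standard default), 0 interpolates the
    input exactly.  The endpoints — the two bottom landmarks — are held
    fixed by heavy weighting and snapped exactly after evaluation.
    ``params`` overrides the ``n_out`` uniform evaluation grid with
    explicit normalized parameter values in [0, 1]; the input points'
    own parameters are their normalized cumulative chord lengths.
    """
    pts = contour.points
    if len(pts) < 4:
        raise ValidationError("B-spline smoothing needs at least 4 points")
    if smoothing is None:
        smoothing = float(len(pts))
    if smoothing < 0:
        raise ValidationError("smoothing must be non-negative")
    if n_out < 2:
        raise ValidationError("n_out must be >= 2")
    u = chord_parameters(pts)
    weights = np.ones(len(pts))
    weights[0] = weights[-1] = 1e6
    tck, _ = interpolate.splprep(
        [pts[:, 0], pts[:, 1]], u=u, w=weights, s=smoothing, k=3
    )
    uu = np.linspace(0.0, 1.0, n_out) if params is None else np.asarray(params, dtype=float)
    rr, cc = interpolate.splev(uu, tck)
    out = np.column_stack([rr, cc])
    if uu[0] == 0.0:
        out[0] = pts[0]
    if uu[-1] == 1.0:
        out[-1] = pts[-1]
    return EndocardialContour(points=out)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    """All artifacts of one end-to-end segmentation run."""

    contour: EndocardialContour
    raw_contour: EndocardialContour
    left_wall: WallCurve
    right_wall: WallCurve
    cavity_mask: np.ndarray        # from the fitted walls
    predicted_cavity: np.ndarray   # filled final contour
    labels: LabelField             # binarization pasted into frame coords
    labels_masked: LabelField
    denoised: UltrasoundFrame
    crop_offset: Tuple[int, int]
    constraints: ConstraintTriplet


def fill_contour(
    contour: EndocardialContour, shape: Tuple[int, int]
) -> np.ndarray:
    """Rasterize the open contour closed by its bottom chord and fill it."""
    from skimage.draw import polygon

    pts = contour.points
    rr, cc = polygon(pts[:, 0], pts[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def segment_endocardium(
    frame: UltrasoundFrame,
    constraints: ConstraintTriplet,
    lv_box,
    config=None,
) -> PipelineResult:
    """Run the full crop -> denoise -> binarize -> fit -> approach chain.

    ``lv_box`` is a :class:`lvseg.geometry.Detection` for the LV region;
    ``config`` a :class:`lvseg.config.PipelineConfig` (defaults used when
    omitted).  All returned coordinates are in full-frame space.
    """
    from .config import PipelineConfig
    from .geometry import crop_lv
    from .mrf import MrfConfig, binarize
    from .preprocess import WienerConfig, wiener_filter

    cfg = config or PipelineConfig()
    sub, offset = crop_lv(frame, lv_box, margin=cfg.crop_margin)
    den = wiener_filter(
        sub, WienerConfig(window=cfg.wiener_window, noise_variance=cfg.wiener_noise)
    )
    lab_crop = binarize(
        den,
        MrfConfig(
            beta=cfg.beta,
            neighborhood=cfg.neighborhood,
            max_sweeps=cfg.max_sweeps,
            label_change_tol=cfg.label_change_tol,
            seed=cfg.seed,
        ),
    )
    # paste the crop labeling into a full-frame canvas
    full = np.zeros(frame.shape, dtype=lab_crop.labels.dtype)
    if lab_crop.myocardium_label == 0:
        full[:] = 1
    r0, c0 = offset
    hh, ww = lab_crop.labels.shape
    full[r0 : r0 + hh, c0 : c0 + ww] = lab_crop.labels
    labels = LabelField(
        labels=full,
        myocardium_label=lab_crop.myocardium_label,
        energy_history=lab_crop.energy_history,
        sweeps=lab_crop.sweeps,
    )
    clean = remove_small_components(labels, cfg.min_component)

    left_pts, right_pts = sample_wall_points(clean, constraints)
    left = fit_wall_constrained(
        left_pts,
        np.array([constraints.apex, constraints.lower_left]),
        degree=cfg.degree,
        side="left",
    )
    right = fit_wall_constrained(
        right_pts,
        np.array([constraints.apex, constraints.lower_right]),
        degree=cfg.degree,
        side="right",
    )
    cavity = build_cavity_mask(left, right, constraints, frame.shape)
    masked = mask_binary(clean, cavity, cfg.mask_dilation, cfg.min_component)
    raw = approach_endocardium(masked, constraints, cavity)
    smooth = smooth_bspline(raw, cfg.spline_smoothing, cfg.spline_n_out)
    predicted = fill_contour(smooth, frame.shape)
    return PipelineResult(
        contour=smooth,
        raw_contour=raw,
        left_wall=left,
        right_wall=right,
        cavity_mask=cavity,
        predicted_cavity=predicted,
        labels=labels,
        labels_masked=masked,
        denoised=den,
        crop_offset=offset,
        constraints=constraints,
    )
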