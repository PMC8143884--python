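"""Synthetic apical-view LV phantoms with exact ground truth.

A phantom frame shows a dark blood-filled cavity bounded by a bright
U-shaped myocardial band on a mid-gray background, the geometry every
downstream stage assumes.  The two walls are cubic polynomials (column
as a function of row) from the same family the contour stage fits, so
exact parameter recovery is testable; the mitral (bottom) side is left
open and the ground-truth endocardial contour runs lower_left -> apex ->
lower_right, matching the three landmark points.

Speckle is modeled as independent multiplicative gamma noise with mean 1
and shape ``k`` (larger k = weaker speckle), the standard first-order
surrogate for fully developed ultrasound speckle; optional elliptical
dropout patches on the myocardium emulate signal-loss artifacts.  All
randomness is seeded and rendering is bit-reproducible.

Pixel rasterization convention: a pixel ``(r, c)`` is cavity iff
``L(r) < c < R(r)`` strictly (and above the bottom chord), so the
continuous wall curve always passes between the innermost myocardium
pixel and the outermost cavity pixel — sub-pixel edge sampling is then
unbiased.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree
from skimage.draw import ellipse as draw_ellipse

from .contour import EndocardialContour
from .errors import ValidationError
from .frame import UltrasoundFrame
from .geometry import ConstraintTriplet, Detection


@dataclass
class PhantomSpec:
    """Complete description of one synthetic frame.

    Wall coefficient vectors are raw-pixel-row cubics in
    ``numpy.polyval`` order: ``col = a1*r^3 + a2*r^2 + a3*r + a4``.
    """

    image_height: int = 192
    image_width: int = 192
    apex_point: Tuple[float, float] = (32.0, 96.0)
    bottom_left: Tuple[float, float] = (158.0, 62.0)
    bottom_right: Tuple[float, float] = (158.0, 130.0)
    wall_coeffs_left: Optional[np.ndarray] = None
    wall_coeffs_right: Optional[np.ndarray] = None
    myocardium_thickness: float = 10.0
    intensity_myocardium: float = 180.0
    intensity_cavity: float = 30.0
    intensity_background: float = 60.0
    speckle_shape: Optional[float] = 10.0  # None disables speckle
    artifact_count: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wall_coeffs_left is None or self.wall_coeffs_right is None:
            left, right = _default_wall_cubics(
                self.apex_point, self.bottom_left, self.bottom_right
            )
            if self.wall_coeffs_left is None:
                self.wall_coeffs_left = left
            if self.wall_coeffs_right is None:
                self.wall_coeffs_right = right
        self.wall_coeffs_left = np.asarray(self.wall_coeffs_left, dtype=float)
        self.wall_coeffs_right = np.asarray(self.wall_coeffs_right, dtype=float)
        self.validate()

    def validate(self) -> None:
        ar, _ = self.apex_point
        if not (ar < self.bottom_left[0] and ar < self.bottom_right[0]):
            raise ValidationError("apex_point: apex row must be above both bottom rows")
        if not self.bottom_left[1] < self.bottom_right[1]:
            raise ValidationError("bottom_left: must be left of bottom_right")
        for name in ("intensity_myocardium", "intensity_cavity", "intensity_background"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValidationError(f"{name}: must be in [0, 255], got {v}")
        if self.myocardium_thickness < 2:
            raise ValidationError("myocardium_thickness: must be >= 2 px")
        if self.speckle_shape is not None:
            if not math.isfinite(self.speckle_shape):
                self.speckle_shape = None  # infinite shape = no speckle
            elif self.speckle_shape <= 0:
                raise ValidationError("speckle_shape: must be positive")
        if self.artifact_count < 0:
            raise ValidationError("artifact_count: must be non-negative")
        if self.wall_coeffs_left.shape != (4,) or self.wall_coeffs_right.shape != (4,):
            raise ValidationError("wall_coeffs_left/right: need 4 cubic coefficients")
        gap = abs(
            np.polyval(self.wall_coeffs_left, self.apex_point[0])
            - np.polyval(self.wall_coeffs_right, self.apex_point[0])
        )
        if gap > 1.0:
            raise ValidationError(
                f"wall_coeffs_left/right: walls must meet at the apex row "
                f"within 1 px (gap {gap:.2f})"
            )

    def left_wall(self, rows: np.ndarray) -> np.ndarray:
        return np.polyval(self.wall_coeffs_left, rows)

    def right_wall(self, rows: np.ndarray) -> np.ndarray:
        return np.polyval(self.wall_coeffs_right, rows)


@dataclass
class PhantomTruth:
    """Rendered frame with exact ground truth."""

    frame: UltrasoundFrame
    cavity_mask: np.ndarray
    myocardium_mask: np.ndarray
    endocardium: EndocardialContour
    constraints: ConstraintTriplet
    lv_box: Detection
    spec: PhantomSpec
    template: np.ndarray  # noise-free 3-level image, uint8


def _default_wall_cubics(
    apex: Tuple[float, float],
    bottom_left: Tuple[float, float],
    bottom_right: Tuple[float, float],
    bulge_left: Tuple[float, float] = (10.0, 8.0),
    bulge_right: Tuple[float, float] = (10.0, 8.0),
) -> Tuple[np.ndarray, np.ndarray]:
    """Exact cubics through apex, bottom and two bulged interior points."""
    ar, ac = apex

    def one_side(bottom, bulges, sign):
        br, bc = bottom
        rows = np.array([ar, ar + (br - ar) / 3.0, ar + 2.0 * (br - ar) / 3.0, br])
        base = np.interp(rows, [ar, br], [ac, bc])
        cols = base + sign * np.array([0.0, bulges[0], bulges[1], 0.0])
        return np.polyfit(rows, cols, 3)

    return one_side(bottom_left, bulge_left, -1.0), one_side(bottom_right, bulge_right, +1.0)


def _chord_row(spec: PhantomSpec, cols: np.ndarray) -> np.ndarray:
    """Row of the open-bottom chord, linearly extended across all columns."""
    (r1, c1), (r2, c2) = spec.bottom_left, spec.bottom_right
    slope = (r2 - r1) / (c2 - c1)
    return r1 + slope * (np.asarray(cols, dtype=float) - c1)


def _truth_masks(spec: PhantomSpec) -> Tuple[np.ndarray, np.ndarray]:
    h, w = spec.image_height, spec.image_width
    apex_r = spec.apex_point[0]
    cavity = np.zeros((h, w), dtype=bool)
    cols_all = np.arange(w)
    chord = _chord_row(spec, cols_all)
    r_lo = int(math.ceil(apex_r))
    r_hi = min(h - 1, int(math.floor(max(spec.bottom_left[0], spec.bottom_right[0]))))
    for r in range(r_lo, r_hi + 1):
        lc = float(spec.left_wall(r))
        rc = float(spec.right_wall(r))
        c0 = max(0, int(math.floor(lc)) + 1)  # strictly right of the left wall
        c1 = min(w - 1, int(math.ceil(rc)) - 1)  # strictly left of the right wall
        if c1 < c0:
            continue
        sel = np.arange(c0, c1 + 1)
        sel = sel[r <= chord[sel] + 1e-9]
        cavity[r, sel] = True

    # dense boundary samples for the distance band
    curve = _dense_endocardium(spec, step=0.25)
    tree = cKDTree(curve)
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pix = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    dist, _ = tree.query(pix, workers=-1)
    near = (dist <= spec.myocardium_thickness).reshape(h, w)
    below_chord = rr > (chord[None, :] + 1e-9)
    myocardium = near & ~cavity & ~below_chord
    return cavity, myocardium


def _dense_endocardium(spec: PhantomSpec, step: float = 0.5) -> np.ndarray:
    """Ordered samples lower_left -> apex -> lower_right along the walls."""
    ar = spec.apex_point[0]
    bl_r, br_r = spec.bottom_left[0], spec.bottom_right[0]
    rows_l = np.arange(bl_r, ar, -step)
    rows_r = np.arange(ar, br_r, step)[1:]
    apex_col = 0.5 * (spec.left_wall(np.array([ar]))[0] + spec.right_wall(np.array([ar]))[0])
    pts = [np.column_stack([rows_l, spec.left_wall(rows_l)])]
    pts.append(np.array([[ar, apex_col]]))
    pts.append(np.column_stack([rows_r, spec.right_wall(rows_r)]))
    pts.append(np.array([[br_r, spec.right_wall(np.array([br_r]))[0]]]))
    return np.vstack(pts)


def render_template(spec: PhantomSpec) -> np.ndarray:
    """The noise-free 3-level intensity image (uint8)."""
    cavity, myocardium = _truth_masks(spec)
    img = np.full(
        (spec.image_height, spec.image_width),
        spec.intensity_background,
        dtype=float,
    )
    img[myocardium] = spec.intensity_myocardium
    img[cavity] = spec.intensity_cavity
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def render_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Render a frame with speckle and artifacts plus its ground truth.

    The same spec (including seed) always renders bit-identical output.
    """
    spec.validate()
    cavity, myocardium = _truth_masks(spec)
    template = render_template(spec)
    rng = np.random.default_rng(spec.seed)
    img = template.astype(float)
    if spec.speckle_shape is not None:
        k = float(spec.speckle_shape)
        img = img * rng.gamma(shape=k, scale=1.0 / k, size=img.shape)
    myo_idx = np.argwhere(myocardium)
    for _ in range(spec.artifact_count):
        if len(myo_idx) == 0:
            break
        r0, c0 = myo_idx[rng.integers(len(myo_idx))]
        a = rng.uniform(2.0, 6.0)
        b = rng.uniform(2.0, 6.0)
        theta = rng.uniform(0.0, math.pi)
        rr, cc = draw_ellipse(r0, c0, a, b, shape=img.shape, rotation=theta)
        img[rr, cc] = 0.2 * img[rr, cc] + 0.8 * spec.intensity_cavity
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    endo = EndocardialContour(points=_dense_endocardium(spec, step=0.5))
    constraints = ConstraintTriplet(
        apex=tuple(spec.apex_point),
        lower_left=tuple(spec.bottom_left),
        lower_right=tuple(spec.bottom_right),
    )
    lv = cavity | myocardium
    rows = np.nonzero(lv.any(axis=1))[0]
    cols = np.nonzero(lv.any(axis=0))[0]
    r0b, r1b = int(rows[0]), int(rows[-1])
    c0b, c1b = int(cols[0]), int(cols[-1])
    lv_box = Detection(
        cx=0.5 * (c0b + c1b),
        cy=0.5 * (r0b + r1b),
        w=float(c1b - c0b + 1),
        h=float(r1b - r0b + 1),
        conf=1.0,
        class_id="LV",
    )
    return PhantomTruth(
        frame=UltrasoundFrame(pixels=pixels, bit_depth=8),
        cavity_mask=cavity,
        myocardium_mask=myocardium,
        endocardium=endo,
        constraints=constraints,
        lv_box=lv_box,
        spec=spec,
        template=template,
    )


def perturb_constraints(
    truth: PhantomTruth, sigma: float, seed: int
) -> ConstraintTriplet:
    """Displace each landmark by N(0, sigma^2) per axis, clamped in-frame.

    Emulates detector localization error for robustness studies; with
    ``sigma=0`` the exact ground-truth triplet is returned.
    """
    if sigma < 0:
        raise ValidationError("sigma must be non-negative")
    if sigma == 0:
        return truth.constraints
    rng = np.random.default_rng(seed)
    h, w = truth.frame.shape
    pts = truth.constraints.as_array() + rng.normal(0.0, sigma, size=(3, 2))
    pts[:, 0] = np.clip(pts[:, 0], 0, h - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0, w - 1)
    return ConstraintTriplet(
        apex=tuple(pts[0]), lower_left=tuple(pts[1]), lower_right=tuple(pts[2])
    )


def random_spec(seed: int, **overrides) -> PhantomSpec:
    """Draw a random in-family phantom around the default geometry.

    Apex and bottom landmarks, wall bulges and thickness vary within
    anatomically plausible (for the 192 px canvas) ranges; keyword
    overrides pass straight into :class:`PhantomSpec`.
    """
    rng = np.random.default_rng(seed)
    apex = (rng.uniform(26.0, 40.0), rng.uniform(88.0, 104.0))
    bottom_row = rng.uniform(150.0, 164.0)
    bl = (bottom_row, rng.uniform(54.0, 72.0))
    br = (bottom_row, rng.uniform(120.0, 138.0))
    left, right = _default_wall_cubics(
        apex,
        bl,
        br,
        bulge_left=(rng.uniform(6.0, 14.0), rng.uniform(4.0, 12.0)),
        bulge_right=(rng.uniform(6.0, 14.0), rng.uniform(4.0, 12.0)),
    )
    params = dict(
        apex_point=apex,
        bottom_left=bl,
        bottom_right=br,
        wall_coeffs_left=left,
        wall_coeffs_right=right,
        myocardium_thickness=rng.uniform(8.0, 13.0),
        seed=seed,
    )
    params.update(overrides)
    return PhantomSpec(**params)
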