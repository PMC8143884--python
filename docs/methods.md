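# Methods

This note records the models, conventions and design choices behind
`lvseg`, in the order the pipeline runs them, followed by what the
synthetic phantoms do and do not establish about clinical data.

## Coordinate and rasterization conventions

All coordinates are 0-based `(row, col)` with row increasing downward
and half-open image bounds. A wall curve is a polynomial
`col = F(row)` — near-vertical walls make column-as-function-of-row the
only single-valued choice. Phantom masks use a strict-interior
rasterization: a pixel is cavity iff `L(r) < c < R(r)` (and above the
mitral chord), so the continuous wall always passes between the
innermost myocardium pixel and the outermost cavity pixel. Wall
samples and ray-cast contour points are placed on that half-integer
edge (innermost myocardium pixel ± 0.5 px); this makes the quantization
error of a sampled edge zero-mean, which is what lets the least-squares
fit recover generating curves to well under half a pixel.

## Wiener denoising

Per-pixel local mean and **population** variance over a centered window
(default 5×5), edge replication at the borders so the output shape
equals the input. The noise floor ν² defaults to the mean of all local
window variances (the classic adaptive-Wiener estimate). The raw gain
`(σ² − ν²)/σ²` is clamped to `[0, 1]`: below the noise floor the filter
outputs the local mean rather than over-shrinking past it, so the
output is always a convex combination of pixel and local mean
(the shrinkage property `|b − μ| ≤ |a − μ|` is asserted in tests).
Output is clipped to the frame's bit-depth range.

## MRF binarization

* **Model.** Two classes (myocardium = the brighter class, it is
  echogenic). Gaussian likelihood energy per pixel with per-class mean
  and variance (variance floored at 1e-4); homogeneous pairwise Potts
  prior with weight β (default 0.7) over an 8-connected neighborhood
  (second-order system, smoother boundaries; 4-connected available).
  Temperature T = 1 by default and only rescales the energy.
* **Initialization.** Two-class Lloyd K-means on intensities. Centroids
  start at the 1st/99th intensity percentiles. This is deterministic
  and converges reliably to the dark/bright split; randomly seeded
  centroids can fall into a local optimum that merges the bright tissue
  with mid-gray background, which shifts the binarization boundary into
  the cavity by the denoising blur width (~3 px) — observed, and the
  reason the initialization is not randomized. The `seed` argument is
  retained for API stability.
* **Optimization.** ICM in deterministic raster order (numba kernel);
  each pixel takes the label minimizing its local conditional energy,
  ties keep the current label. After every sweep the class parameters
  are re-estimated as the per-class empirical mean/variance; since the
  Gaussian MLE minimizes exactly the likelihood-energy term, both
  half-steps descend the same objective and the recorded energy history
  is non-increasing (asserted per sweep in tests). A class that empties
  keeps its previous parameters. Stopping: zero flips or 15 sweeps.
* **Oracle.** `exhaustive_map_energy` enumerates all 2^N labelings of
  tiny images (N ≤ 16) through the same `total_energy` definition but
  independently of the ICM path; on 200 well-separated noisy 3×3 images
  ICM matches the global MAP labeling's energy in every case.

## Wall fitting

Cubic least squares with rows affinely rescaled to `[−1, 1]` — a cubic
Vandermonde on raw pixel rows is badly conditioned — and coefficients
stored on the normalized axis with the transform. The constrained fit
minimizes `‖BX − L‖²` subject to `CX = d` through the bordered KKT
system `[[2BᵀB, Cᵀ], [C, 0]]`; the two constraints per side are the
apex and that side's bottom landmark, satisfied to well below 1e-6 px.
The constrained optimum can never beat the unconstrained residual;
both facts are asserted on random systems.

Wall samples come from the binarized field: for each row, the innermost
myocardium pixel on each side of a split line running from the apex to
the midpoint of the two bottom landmarks. A constant split column
misassigns pixels near the apex where the cavity is narrow and
off-center; the apex-anchored split line fixes this, and rows whose
split pixel is itself myocardium (no clean gap) are skipped. Before
sampling, 8-connected myocardium components below 20 px are dropped so
speckle islands cannot pose as the innermost wall pixel.

## Cavity mask and morphological cleanup

The cavity mask is the inclusive set `F_left(r) ≤ c ≤ F_right(r)` for
rows from the apex to the lowest bottom landmark, closed with a 3×3
square to seal rasterization gaps. `mask_binary` then keeps a
myocardium component only if it touches the cavity dilated by 5 px
(square structuring element, implemented as a chessboard-distance
threshold) — the wall band always does — and removes sub-20-px islands
lying entirely inside the cavity. Components are *kept whole* rather
than clipped to the dilated region: the cleanup targets interference
around the cavity, not the outer wall, and clipping would truncate any
wall thicker than the dilation radius.

## Edge approach and smoothing

From each cavity row's midline, horizontal rays run left and right to
the first myocardium pixel; the contour vertex is the last
non-myocardium position (half a pixel short of the hit). Rows above the
first row where both rays hit are covered by a radial fan of 11 rays
(165°…15° in image coordinates, stepping 0.5 px) from that row's
midline point, which handles the apex cap where horizontal rays are
undefined. Rows and rays that exit without a hit are skipped and
logged; failure of more than half the attempted rows aborts with an
extraction error. The three constraint points enter the vertex list
verbatim (first, apex, last).

Smoothing is a cubic B-spline under chord-length parameterization
(FITPACK), evaluated at 100 uniform parameter values. The smoothing
factor defaults to the number of input vertices (the standard FITPACK
heuristic). The two endpoints — the bottom landmarks — are pinned by a
1e6 relative weight and snapped exactly after evaluation; with
smoothing 0 the spline interpolates the input.

## Metrics

Dice on pixel counts; MAD and HD as point-set distances over the
sampled contour vertices (no segment interpolation — contours should be
resampled densely, the pipeline outputs 100 vertices). Millimetre
reports scale coordinates per axis by the pixel spacing before
distances are taken; without spacing, reports say `px`. Detection
matching is greedy in confidence order with an *inclusive* IOU
threshold (a match requires IOU ≥ 0.5 by default). AP integrates the
all-point interpolated precision envelope; mAP is the unweighted mean
over classes.

## Phantom generator

The generator emulates a single apical-view frame: bright U-shaped
myocardial band (default mean 180), dark cavity (30), mid-gray
background (60), walls drawn from random in-family cubics through the
apex, the bottom landmark and two bulged interior points on a 192×192
canvas. Speckle is independent multiplicative gamma noise with mean 1
and shape k (default 10, giving a ~32 % coefficient of variation —
strong but realistic fully-developed speckle); dropout artifacts are
elliptical patches (2–6 px axes) on the myocardium blended 80 % toward
the cavity level (default 2 per frame). Detector error is emulated by
Gaussian landmark perturbation (σ = 2 px in the robustness suites).
The default myocardium level of 180 leaves headroom for the speckle's
upper tail before 8-bit clipping; at 200 the clipped tail biases the
regional mean by more than 5 %.

What the phantoms do **not** model: attenuation and shadowing, the
mitral-valve apparatus, temporal coherence across a cine loop,
anisotropic point-spread blur, and out-of-family wall shapes. Passing
the phantom suites therefore demonstrates the internal correctness and
noise robustness of the chain — exact wall recovery in the noise-free
limit, graceful degradation under speckle — not clinical-grade accuracy
on real echocardiograms, whose noise statistics are uncharacterized
here. Phantom difficulty levels are conventions, not calibrations.

## Numerical choices and degenerate inputs

* Population (divide-by-N) variances throughout.
* K-means convergence 1e-6 or 100 iterations; anchor K-means (1−IOU
  metric) 300 iterations.
* ICM tie-break keeps the current label; raster order fixed.
* Constant images raise a degenerate-input error from every binarizer.
* Identical constraint rows demanding different columns raise a
  constraint-conflict error; crossing fitted walls raise a geometry
  error naming the first offending row.
* Problem sizes in the validation suites — 200 3×3 oracle images, 50
  noise-free recovery phantoms, 100 random fit systems, 20 end-to-end
  phantoms at 192×192 — were chosen so each property is measured with
  comfortable statistical margin while the whole suite stays
  interactive (tens of seconds).

## Known limitations

* The detector itself is out of scope: detections enter via JSON (or
  phantom truth), and anchor clustering / box decoding are provided as
  library math, not as a trained model.
* Single-frame only; no epicardium, volumes, strain or ejection
  fraction.
* The edge approach assumes one cavity between two walls; it has no
  recovery path for grossly wrong binarizations (it fails loudly
  instead).
* MAD/HD are vertex-set distances; extremely sparse contours would need
  resampling before evaluation.
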