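"""Markov-random-field binarization of the LV subimage.

The myocardium is echogenic (bright) while the blood pool is dark, so a
two-class labeling of the denoised crop separates muscle from
background.  The labeling ``x`` is the hidden field of a posterior
``P(x | y) ~ exp(-E(x | y) / T)`` whose energy splits into a Gaussian
likelihood term per pixel and a homogeneous pairwise Potts prior::

    E(x | y) = sum_i [ (y_i - mu_{x_i})^2 / (2 sigma_{x_i}^2)
                       + 1/2 log(2 pi sigma_{x_i}^2) ]
             + beta * sum_{<i,j>} 1[x_i != x_j]

all divided by the temperature ``T``.  MAP estimation is performed by
iterated conditional modes (ICM): deterministic raster-order sweeps in
which each pixel takes the label minimizing its local conditional
energy given the current neighbors.  The class means/variances are
re-estimated from the current labeling after every sweep; since the
per-class Gaussian MLE minimizes exactly the likelihood energy, both
half-steps descend the same objective and the total energy is
non-increasing across sweeps.

The initial label field comes from a seeded two-class K-means on the
intensities, and plain Otsu / K-means binarizers are provided as
baselines for head-to-head comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import List, Optional, Tuple

import numpy as np
from numba import njit
from skimage.filters import threshold_otsu

from .errors import DegenerateInputError, ValidationError
from .frame import UltrasoundFrame

_VAR_FLOOR = 1e-4


@dataclass
class LabelField:
    """A binary per-pixel labeling plus optimization bookkeeping."""

    labels: np.ndarray  # 2-D int array over {0, 1}
    myocardium_label: int = 1
    energy_history: List[float] = field(default_factory=list)
    sweeps: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValidationError("label field must be 2-D")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("labels must be 0/1")
        if self.myocardium_label not in (0, 1):
            raise ValidationError("myocardium_label must be 0 or 1")

    @property
    def myocardium_mask(self) -> np.ndarray:
        return self.labels == self.myocardium_label


@dataclass
class ClassModel:
    """Per-class Gaussian intensity model (mean, variance) for 2 classes."""

    means: np.ndarray  # shape (2,)
    variances: np.ndarray  # shape (2,), floored at a small epsilon

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float).reshape(2)
        self.variances = np.maximum(
            np.asarray(self.variances, dtype=float).reshape(2), _VAR_FLOOR
        )


@dataclass
class MrfConfig:
    """MRF/ICM knobs.

    beta
        Pairwise Potts weight; 0 disables spatial regularization.
    temperature
        Gibbs temperature T; 1 by convention.
    neighborhood
        4- or 8-connected clique system; 8 gives smoother boundaries.
    max_sweeps / label_change_tol
        ICM stops when the number of flips in a sweep drops to
        ``label_change_tol`` or after ``max_sweeps`` raster sweeps.
    seed
        Seeds the K-means initialization.
    """

    beta: float = 0.7
    temperature: float = 1.0
    neighborhood: int = 8
    max_sweeps: int = 15
    label_change_tol: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValidationError("beta must be non-negative")
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")
        if self.neighborhood not in (4, 8):
            raise ValidationError("neighborhood must be 4 or 8")
        if self.max_sweeps < 1:
            raise ValidationError("max_sweeps must be >= 1")
        if self.label_change_tol < 0:
            raise ValidationError("label_change_tol must be non-negative")


# ---------------------------------------------------------------------------
# K-means initialization
# ---------------------------------------------------------------------------

def kmeans_init(
    frame: UltrasoundFrame, seed: int = 0
) -> Tuple[LabelField, ClassModel]:
    """Two-class Lloyd K-means on the raw intensities.

    Returns the initial label field and the per-cluster Gaussian model.
    The brighter cluster is marked as myocardium.  Centroids start at
    the 1st/99th intensity percentiles: deterministic, and Lloyd then
    reliably converges to the dark/bright split (random initialization
    can fall into a local optimum that merges the bright tissue with
    mid-gray background).  ``seed`` is kept in the signature for API
    stability; the initialization is deterministic.
    """
    a = frame.as_float()
    values = a.ravel()
    uniq = np.unique(values)
    if uniq.size < 2:
        raise DegenerateInputError("constant image has no 2-class structure")

    centers = np.percentile(values, [1.0, 99.0]).astype(float)
    if centers[0] == centers[1]:
        centers = np.array([float(uniq[0]), float(uniq[-1])])
    for _ in range(100):
        assign = (np.abs(values - centers[1]) < np.abs(values - centers[0])).astype(np.int8)
        new_centers = centers.copy()
        for j in (0, 1):
            sel = values[assign == j]
            if sel.size:
                new_centers[j] = sel.mean()
        if np.max(np.abs(new_centers - centers)) < 1e-6:
            centers = new_centers
            break
        centers = new_centers
    assign = (np.abs(values - centers[1]) < np.abs(values - centers[0])).astype(np.int8)

    means = np.empty(2)
    variances = np.empty(2)
    for j in (0, 1):
        sel = values[assign == j]
        if sel.size == 0:
            # one cluster collapsed; split on the midpoint instead
            raise DegenerateInputError("K-means collapsed to a single cluster")
        means[j] = sel.mean()
        variances[j] = sel.var()
    model = ClassModel(means=means, variances=variances)
    labels = assign.reshape(a.shape)
    myo = int(np.argmax(means))
    return LabelField(labels=labels, myocardium_label=myo), model


# ---------------------------------------------------------------------------
# Energies
# ---------------------------------------------------------------------------

def _likelihood_energy_maps(a: np.ndarray, model: ClassModel) -> np.ndarray:
    """Per-pixel Gaussian energy for each label; shape (2, H, W)."""
    out = np.empty((2,) + a.shape)
    for l in (0, 1):
        mu, var = model.means[l], model.variances[l]
        out[l] = (a - mu) ** 2 / (2.0 * var) + 0.5 * np.log(2.0 * np.pi * var)
    return out


def _potts_disagreements(labels: np.ndarray, neighborhood: int) -> int:
    """Number of unordered neighbor pairs with differing labels."""
    n = int(np.sum(labels[:, 1:] != labels[:, :-1]))
    n += int(np.sum(labels[1:, :] != labels[:-1, :]))
    if neighborhood == 8:
        n += int(np.sum(labels[1:, 1:] != labels[:-1, :-1]))
        n += int(np.sum(labels[1:, :-1] != labels[:-1, 1:]))
    return n


def total_energy(
    frame: UltrasoundFrame,
    labels: LabelField,
    model: ClassModel,
    cfg: MrfConfig,
) -> float:
    """Posterior energy E(y|x) + E(x), divided by the temperature."""
    a = frame.as_float()
    if a.shape != labels.labels.shape:
        raise ValidationError("frame and label field shapes differ")
    emaps = _likelihood_energy_maps(a, model)
    lab = labels.labels
    lik = float(np.where(lab == 1, emaps[1], emaps[0]).sum())
    potts = cfg.beta * _potts_disagreements(lab, cfg.neighborhood)
    return (lik + potts) / cfg.temperature


# ---------------------------------------------------------------------------
# ICM
# ---------------------------------------------------------------------------

@njit(cache=False)
def _icm_sweep(labels, a, mu, var, beta, eight):  # pragma: no cover - numba
    h, w = labels.shape
    flips = 0
    log2pi = np.log(2.0 * np.pi)
    for r in range(h):
        for c in range(w):
            e0 = (a[r, c] - mu[0]) ** 2 / (2.0 * var[0]) + 0.5 * (log2pi + np.log(var[0]))
            e1 = (a[r, c] - mu[1]) ** 2 / (2.0 * var[1]) + 0.5 * (log2pi + np.log(var[1]))
            n0 = 0
            n1 = 0
            for dr in range(-1, 2):
                for dc in range(-1, 2):
                    if dr == 0 and dc == 0:
                        continue
                    if not eight and dr != 0 and dc != 0:
                        continue
                    rr = r + dr
                    cc = c + dc
                    if 0 <= rr < h and 0 <= cc < w:
                        if labels[rr, cc] == 0:
                            n1 += 1  # label 1 would disagree
                        else:
                            n0 += 1  # label 0 would disagree
            e0 += beta * n0
            e1 += beta * n1
            cur = labels[r, c]
            if cur == 0:
                if e1 < e0:
                    labels[r, c] = 1
                    flips += 1
            else:
                if e0 < e1:
                    labels[r, c] = 0
                    flips += 1
    return flips


def _reestimate(
    a: np.ndarray, labels: np.ndarray, model: ClassModel
) -> ClassModel:
    """Per-class empirical mean/variance; empty classes keep old params."""
    means = model.means.copy()
    variances = model.variances.copy()
    for j in (0, 1):
        sel = a[labels == j]
        if sel.size:
            means[j] = sel.mean()
            variances[j] = sel.var()
    return ClassModel(means=means, variances=variances)


def icm_segment(
    frame: UltrasoundFrame,
    init: LabelField,
    model: ClassModel,
    cfg: MrfConfig = MrfConfig(),
    update_model: bool = True,
) -> LabelField:
    """Minimize the posterior energy by raster-order ICM sweeps.

    The returned field records the energy after initialization and after
    every sweep in ``energy_history``; that sequence is non-increasing.
    With ``update_model=False`` the class model is held fixed (used for
    oracle comparisons against exhaustive MAP search).
    """
    a = frame.as_float()
    if a.shape != init.labels.shape:
        raise ValidationError("frame and init label field shapes differ")
    labels = init.labels.astype(np.int8).copy()
    cur_model = ClassModel(model.means.copy(), model.variances.copy())
    history = [total_energy(frame, LabelField(labels, init.myocardium_label), cur_model, cfg)]
    eight = cfg.neighborhood == 8
    sweeps = 0
    # beta enters the local energy scaled the same way as in total_energy;
    # the common 1/T factor does not change the argmin, so the kernel
    # works with unscaled energies.
    for _ in range(cfg.max_sweeps):
        flips = _icm_sweep(
            labels, a, cur_model.means, cur_model.variances, cfg.beta, eight
        )
        sweeps += 1
        if update_model:
            cur_model = _reestimate(a, labels, cur_model)
        history.append(
            total_energy(frame, LabelField(labels, init.myocardium_label), cur_model, cfg)
        )
        if flips <= cfg.label_change_tol:
            break
    myo = int(np.argmax(cur_model.means)) if update_model else init.myocardium_label
    return LabelField(
        labels=labels.astype(init.labels.dtype),
        myocardium_label=myo,
        energy_history=history,
        sweeps=sweeps,
    )


def binarize(
    frame: UltrasoundFrame, cfg: MrfConfig = MrfConfig()
) -> LabelField:
    """K-means initialization followed by ICM refinement."""
    init, model = kmeans_init(frame, seed=cfg.seed)
    return icm_segment(frame, init, model, cfg)


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

def otsu_binarize(frame: UltrasoundFrame) -> LabelField:
    """Global Otsu threshold; bright side labeled myocardium."""
    a = frame.as_float()
    if np.unique(a).size < 2:
        raise DegenerateInputError("constant image cannot be thresholded")
    thr = threshold_otsu(a)
    labels = (a > thr).astype(np.int8)
    return LabelField(labels=labels, myocardium_label=1)


def kmeans_binarize(frame: UltrasoundFrame, seed: int = 0) -> LabelField:
    """Plain 2-means labeling without MRF refinement."""
    labels, _ = kmeans_init(frame, seed=seed)
    return labels


# ---------------------------------------------------------------------------
# Exhaustive MAP oracle (tiny images only)
# ---------------------------------------------------------------------------

def exhaustive_map_energy(
    frame: UltrasoundFrame,
    model: ClassModel,
    cfg: MrfConfig,
    max_pixels: int = 16,
) -> Tuple[float, np.ndarray]:
    """Global minimum posterior energy by enumerating all 2^N labelings.

    Independent of the ICM path: energies are evaluated with
    :func:`total_energy` over the full labeling set.  Only feasible for
    tiny images (``N <= max_pixels``).
    """
    a = frame.as_float()
    h, w = a.shape
    n = h * w
    if n > max_pixels:
        raise ValidationError(f"exhaustive search limited to {max_pixels} pixels")
    best_e = np.inf
    best_labels: Optional[np.ndarray] = None
    for bits in product((0, 1), repeat=n):
        lab = np.array(bits, dtype=np.int8).reshape(h, w)
        e = total_energy(frame, LabelField(lab), model, cfg)
        if e < best_e:
            best_e = e
            best_labels = lab
    assert best_labels is not None
    return float(best_e), best_labels
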