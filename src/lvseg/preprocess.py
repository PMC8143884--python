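"""Adaptive Wiener speckle suppression.

The filter estimates a local mean ``mu`` and population variance
``sigma2`` in a sliding window around every pixel and shrinks the pixel
toward the local mean in proportion to how much of the local variance
can be attributed to noise::

    b = mu + (sigma2 - nu2) / sigma2 * (a - mu)

With a large local variance (an edge) the gain approaches 1 and the
pixel passes through almost untouched; with a small local variance (a
homogeneous speckle patch) the gain drops and the pixel is pulled to the
local mean.  Wherever ``sigma2 < nu2`` the gain is clamped at 0 so the
output never overshoots past the mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np
from scipy.ndimage import uniform_filter

from .errors import ValidationError
from .frame import UltrasoundFrame


@dataclass
class WienerConfig:
    """Window geometry and noise floor of the adaptive Wiener filter.

    ``noise_variance`` is the speckle variance ``nu2``; the default
    ``"auto"`` estimates it as the mean of all local window variances,
    the classic adaptive-Wiener convention.
    """

    window: Tuple[int, int] = (5, 5)
    noise_variance: Union[float, str] = "auto"

    def __post_init__(self) -> None:
        wr, wc = self.window
        if wr < 1 or wc < 1 or wr % 2 == 0 or wc % 2 == 0:
            raise ValidationError(
                f"window dimensions must be odd and >= 1, got {self.window}"
            )
        if isinstance(self.noise_variance, str):
            if self.noise_variance != "auto":
                raise ValidationError(
                    f"noise_variance must be a number or 'auto', got {self.noise_variance!r}"
                )
        elif self.noise_variance < 0:
            raise ValidationError("noise_variance must be non-negative")


def local_stats(
    pixels: np.ndarray, window: Tuple[int, int]
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-pixel windowed mean and population variance.

    Boundary handling is edge replication, so the output has the same
    shape as the input.
    """
    a = np.asarray(pixels, dtype=np.float64)
    mu = uniform_filter(a, size=window, mode="nearest")
    mu2 = uniform_filter(a * a, size=window, mode="nearest")
    var = np.maximum(mu2 - mu * mu, 0.0)
    return mu, var


def wiener_filter(frame: UltrasoundFrame, cfg: WienerConfig = WienerConfig()) -> UltrasoundFrame:
    """Apply the adaptive Wiener filter to a frame.

    Returns a new frame of the same shape, clipped to the input
    bit-depth range.  With ``noise_variance=0`` the filter is the
    identity; on a constant frame it returns the constant.
    """
    a = frame.as_float()
    mu, var = local_stats(a, cfg.window)
    if cfg.noise_variance == "auto":
        nu2 = float(var.mean())
    else:
        nu2 = float(cfg.noise_variance)
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where(var > 0, (var - nu2) / np.where(var > 0, var, 1.0), 0.0)
    gain = np.clip(gain, 0.0, 1.0)
    b = mu + gain * (a - mu)
    b = np.clip(b, 0.0, float(frame.max_value))
    return frame.with_pixels(b)
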