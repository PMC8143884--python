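"""The in-memory ultrasound frame container.

A frame is a plain 2-D intensity grid.  The pixel coordinate convention
throughout the package is 0-based ``(row, col)`` with row increasing
downward and half-open image bounds, i.e. valid pixel centers are
``0 <= row < height`` and ``0 <= col < width``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import ValidationError


@dataclass
class UltrasoundFrame:
    """A single 2-D grayscale ultrasound frame.

    Parameters
    ----------
    pixels
        2-D array of non-negative intensities.  Stored as provided
        (integer or floating); processing stages work in float64 and
        clip back to the bit-depth range on output.
    bit_depth
        8 or 16; defines the valid intensity range ``[0, 2**bit_depth - 1]``.
    pixel_spacing_mm
        Optional physical spacing ``(row_mm, col_mm)`` used by the
        evaluation metrics to report distances in millimetres.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    pixel_spacing_mm: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValidationError(
                f"frame must be 2-D, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValidationError("frame must have height >= 1 and width >= 1")
        if self.bit_depth not in (8, 16):
            raise ValidationError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if np.any(self.pixels < 0) or np.any(self.pixels > self.max_value):
            raise ValidationError(
                f"intensities must lie in [0, {self.max_value}] for "
                f"bit depth {self.bit_depth}"
            )
        if self.pixel_spacing_mm is not None:
            sr, sc = self.pixel_spacing_mm
            if sr <= 0 or sc <= 0:
                raise ValidationError("pixel_spacing_mm entries must be positive")
            self.pixel_spacing_mm = (float(sr), float(sc))

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    def as_float(self) -> np.ndarray:
        """Return the intensities as a float64 array (a copy)."""
        return np.asarray(self.pixels, dtype=np.float64)

    def with_pixels(self, pixels: np.ndarray) -> "UltrasoundFrame":
        """A new frame with the same metadata and different pixel data."""
        return UltrasoundFrame(
            pixels=pixels,
            bit_depth=self.bit_depth,
            pixel_spacing_mm=self.pixel_spacing_mm,
        )
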