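"""Pipeline configuration.

One flat config object drives the full segmentation chain.  Defaults
follow the method's stated settings: a 5x5 Wiener window, two intensity
classes at temperature 1, polynomial degree 3, IOU threshold 0.5 in the
detection metrics.  YAML configs are validated strictly — unknown keys
are rejected — and CLI flags override file values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import yaml

from .errors import ValidationError

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    # Wiener denoising
    wiener_window: Tuple[int, int] = (5, 5)
    wiener_noise: Union[float, str] = "auto"
    # MRF binarization
    beta: float = 0.7
    neighborhood: int = 8
    max_sweeps: int = 15
    label_change_tol: int = 0
    seed: int = 0
    # wall fitting
    degree: int = 3
    # B-spline smoothing
    spline_smoothing: Optional[float] = None  # None = number of input points
    spline_n_out: int = 100
    # morphology
    mask_dilation: int = 5
    min_component: int = 20
    # cropping
    crop_margin: int = 10
    # physical spacing (row mm, col mm) for metric reports
    pixel_spacing: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        wr, wc = self.wiener_window
        if wr % 2 == 0 or wc % 2 == 0 or wr < 1 or wc < 1:
            raise ValidationError(f"wiener_window must be odd/positive, got {self.wiener_window}")
        if not (isinstance(self.wiener_noise, str) and self.wiener_noise == "auto"):
            if isinstance(self.wiener_noise, str):
                raise ValidationError("wiener_noise must be a number or 'auto'")
            if self.wiener_noise < 0:
                raise ValidationError("wiener_noise must be non-negative")
        if self.beta < 0:
            raise ValidationError("beta must be non-negative")
        if self.neighborhood not in (4, 8):
            raise ValidationError("neighborhood must be 4 or 8")
        if self.max_sweeps < 1:
            raise ValidationError("max_sweeps must be >= 1")
        if self.label_change_tol < 0:
            raise ValidationError("label_change_tol must be non-negative")
        if self.degree < 1:
            raise ValidationError("degree must be >= 1")
        if self.spline_smoothing is not None and self.spline_smoothing < 0:
            raise ValidationError("spline_smoothing must be non-negative")
        if self.spline_n_out < 2:
            raise ValidationError("spline_n_out must be >= 2")
        if self.mask_dilation < 0:
            raise ValidationError("mask_dilation must be non-negative")
        if self.min_component < 0:
            raise ValidationError("min_component must be non-negative")
        if self.crop_margin < 0:
            raise ValidationError("crop_margin must be non-negative")
        if self.pixel_spacing is not None:
            sr, sc = self.pixel_spacing
            if sr <= 0 or sc <= 0:
                raise ValidationError("pixel_spacing entries must be positive")


_FIELDS = {f.name for f in dataclasses.fields(PipelineConfig)}
_TUPLE_FIELDS = {"wiener_window", "pixel_spacing"}


def load_config(path: str) -> PipelineConfig:
    """Load and validate a YAML pipeline config."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"config {path} must be a mapping")
    version = data.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValidationError(f"unsupported config schema_version {version}")
    unknown = set(data) - _FIELDS
    if unknown:
        raise ValidationError(f"unknown config keys: {', '.join(sorted(unknown))}")
    for key in _TUPLE_FIELDS & set(data):
        if data[key] is not None:
            data[key] = tuple(data[key])
    return PipelineConfig(**data)


def dump_config(cfg: PipelineConfig, path: str) -> None:
    data = dataclasses.asdict(cfg)
    data["schema_version"] = SCHEMA_VERSION
    for key in _TUPLE_FIELDS:
        if data[key] is not None:
            data[key] = list(data[key])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
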