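"""File readers and writers.

Frames come in as single-channel PNG or TIFF (8- or 16-bit; RGB is
accepted and converted by luminance).  Masks go out as 8-bit PNG with
foreground = 255; contours as a two-column CSV with header ``row,col``;
reports and detections as JSON with a schema version field.  All writers
round-trip losslessly through their matching reader.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence, Union

import imageio.v3 as iio
import numpy as np

from .contour import EndocardialContour
from .errors import FormatError
from .frame import UltrasoundFrame
from .geometry import ALL_CLASSES, Detection

SCHEMA_VERSION = 1

PathLike = Union[str, Path]


def read_frame(path: PathLike) -> UltrasoundFrame:
    """Read a PNG/TIFF frame; RGB input is converted by luminance."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise FormatError(f"{path}: unreadable image ({exc})") from exc
    if arr.ndim == 3:
        if arr.shape[-1] in (3, 4):
            rgb = arr[..., :3].astype(np.float64)
            arr = np.rint(
                0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
            ).astype(arr.dtype)
        else:
            raise FormatError(
                f"{path}: multi-frame or unsupported channel layout {arr.shape}"
            )
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a 2-D image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise FormatError(f"{path}: unsupported bit depth {arr.dtype}")
    return UltrasoundFrame(pixels=arr, bit_depth=depth)


def write_frame(path: PathLike, frame: UltrasoundFrame) -> None:
    dtype = np.uint8 if frame.bit_depth == 8 else np.uint16
    iio.imwrite(Path(path), np.asarray(frame.pixels, dtype=dtype))


def write_mask(path: PathLike, mask: np.ndarray) -> None:
    """Write a binary mask as 8-bit PNG, foreground = 255."""
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask(path: PathLike) -> np.ndarray:
    frame = read_frame(path)
    return np.asarray(frame.pixels) > 0


def write_contour(path: PathLike, contour: EndocardialContour) -> None:
    """Write a contour as CSV: header ``row,col``, one vertex per line."""
    with open(path, "w") as fh:
        fh.write("row,col\n")
        for r, c in contour.points:
            fh.write(f"{r:.6f},{c:.6f}\n")


def read_contour(path: PathLike) -> EndocardialContour:
    try:
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    except Exception as exc:
        raise FormatError(f"{path}: unreadable contour CSV ({exc})") from exc
    if data.shape[1] != 2:
        raise FormatError(f"{path}: contour CSV must have two columns")
    return EndocardialContour(points=data)


def write_report(path: PathLike, report: dict) -> None:
    payload = {"schema_version": SCHEMA_VERSION, **report}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_detections(path: PathLike) -> List[Detection]:
    """Read the detections JSON contract.

    Format: ``{"image": "...", "detections": [{"class": ..., "cx": ...,
    "cy": ..., "w": ..., "h": ..., "conf": ...}]}`` in pixel units,
    full-frame 0-based coordinates.
    """
    try:
        with open(path) as fh:
            data = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"{path}: unreadable detections JSON ({exc})") from exc
    dets = []
    for i, d in enumerate(data.get("detections", [])):
        cls = d.get("class")
        if cls not in ALL_CLASSES:
            raise FormatError(f"{path}: detection {i} has unknown class {cls!r}")
        dets.append(
            Detection(
                cx=float(d["cx"]),
                cy=float(d["cy"]),
                w=float(d["w"]),
                h=float(d["h"]),
                conf=float(d.get("conf", 1.0)),
                class_id=cls,
            )
        )
    return dets


def write_detections(path: PathLike, dets: Sequence[Detection], image: str = "") -> None:
    payload = {
        "image": image,
        "detections": [
            {
                "class": d.class_id,
                "cx": d.cx,
                "cy": d.cy,
                "w": d.w,
                "h": d.h,
                "conf": d.conf,
            }
            for d in dets
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
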