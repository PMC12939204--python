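"""Image I/O, pixel-to-physical scale calibration, and result tables.

A rib-eye photograph carries no physical units of its own; a reference of
known length placed in the frame (e.g. a 5 cm segment of a vernier caliper)
ties pixels to centimetres.  :class:`ScaleCalibration` holds that single
global conversion factor and every downstream length/area is expressed
through it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import CalibrationError, InputError

__all__ = [
    "RGBImage",
    "ScaleCalibration",
    "CalibratedImage",
    "load_image",
    "save_image",
    "calibrate_scale",
    "px_to_cm",
    "cm_to_px",
    "px2_to_cm2",
    "cm2_to_px2",
    "write_measurements",
    "read_measurements",
    "MEASUREMENT_COLUMNS",
]

#: Column order of the measurement/grade result table.
MEASUREMENT_COLUMNS = (
    "sample_id",
    "length_cm",
    "width_cm",
    "area_cm2",
    "marbling_pct",
    "mean_r",
    "mean_g",
    "mean_b",
    "red_ratio",
    "grade",
)


@dataclass
class RGBImage:
    """An 8-bit/channel RGB raster (H x W x 3, values 0-255), assumed sRGB."""

    pixels: np.ndarray
    source: str = ""
    colorspace: str = "sRGB"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise InputError(f"expected H x W x 3 pixel array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise InputError("image must have at least one row and one column")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise InputError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) in pixels."""
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass(frozen=True)
class ScaleCalibration:
    """Pixel <-> centimetre conversion from an in-image reference segment."""

    px_per_cm: float
    known_distance_cm: float
    reference_points: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        if not (self.px_per_cm > 0 and math.isfinite(self.px_per_cm)):
            raise CalibrationError(f"px_per_cm must be positive, got {self.px_per_cm}")


@dataclass
class CalibratedImage:
    """An RGB image together with its (single, global) scale calibration."""

    image: RGBImage
    calibration: ScaleCalibration


def load_image(path: str | Path) -> RGBImage:
    """Read a JPEG/PNG file into an :class:`RGBImage`.

    Grayscale sources are replicated to three channels; an alpha channel is
    dropped.  Anything that cannot be decoded to an 8-bit raster raises
    :class:`InputError` naming the offending path.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - decoder errors vary by plugin
        raise InputError(f"cannot read image {path!s}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.dtype != np.uint8:
        raise InputError(f"{path!s}: only 8-bit/channel images are supported (got {arr.dtype})")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise InputError(f"{path!s}: unsupported image layout with shape {arr.shape}")
    return RGBImage(pixels=arr.copy(), source=str(path))


def save_image(pixels: np.ndarray | RGBImage, path: str | Path) -> None:
    """Write an RGB raster or a boolean mask (as 0/255) to PNG/JPEG."""
    if isinstance(pixels, RGBImage):
        pixels = pixels.pixels
    arr = np.asarray(pixels)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    iio.imwrite(Path(path), arr)


def calibrate_scale(
    p1: Sequence[float], p2: Sequence[float], known_distance_cm: float
) -> ScaleCalibration:
    """Build a :class:`ScaleCalibration` from two pixel points a known distance apart.

    ``px_per_cm`` is the Euclidean pixel distance between ``p1`` and ``p2``
    divided by ``known_distance_cm``; orientation of the segment is
    irrelevant.
    """
    if known_distance_cm <= 0 or not math.isfinite(known_distance_cm):
        raise CalibrationError(f"known distance must be positive, got {known_distance_cm}")
    (x1, y1), (x2, y2) = (float(p1[0]), float(p1[1])), (float(p2[0]), float(p2[1]))
    dist_px = math.hypot(x2 - x1, y2 - y1)
    if dist_px == 0:
        raise CalibrationError("reference points coincide; cannot calibrate scale")
    return ScaleCalibration(
        px_per_cm=dist_px / known_distance_cm,
        known_distance_cm=known_distance_cm,
        reference_points=((x1, y1), (x2, y2)),
    )


def px_to_cm(n_px: float, cal: ScaleCalibration) -> float:
    """Convert a pixel length to centimetres."""
    return float(n_px) / cal.px_per_cm


def cm_to_px(n_cm: float, cal: ScaleCalibration) -> float:
    """Convert a centimetre length to pixels."""
    return float(n_cm) * cal.px_per_cm


def px2_to_cm2(n_px2: float, cal: ScaleCalibration) -> float:
    """Convert a pixel-count area to cm^2."""
    return float(n_px2) / cal.px_per_cm**2


def cm2_to_px2(n_cm2: float, cal: ScaleCalibration) -> float:
    """Convert a cm^2 area to square pixels."""
    return float(n_cm2) * cal.px_per_cm**2


def _rows_to_frame(records) -> pd.DataFrame:
    rows = []
    for item in records:
        record, grade = item if isinstance(item, tuple) else (item, None)
        row = {
            "sample_id": record.sample_id,
            "length_cm": record.length_cm,
            "width_cm": record.width_cm,
            "area_cm2": record.area_cm2,
            "marbling_pct": record.marbling_pct,
            "mean_r": record.mean_r,
            "mean_g": record.mean_g,
            "mean_b": record.mean_b,
            "red_ratio": record.red_ratio,
            "grade": "" if grade is None else getattr(grade, "final_grade", str(grade)),
        }
        rows.append(row)
    return pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))


def write_measurements(records, path: str | Path) -> None:
    """Write measurement records (optionally paired with grade results) to disk.

    ``records`` is a sequence of ``MeasurementRecord`` or of
    ``(MeasurementRecord, GradeResult)`` tuples.  ``.json`` paths get a JSON
    array of row objects; anything else gets CSV with a fixed header.  The
    table round-trips losslessly through :func:`read_measurements`.
    """
    records = list(records)
    if not records:
        raise InputError("no records to write")
    frame = _rows_to_frame(records)
    path = Path(path)
    try:
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(frame.to_dict(orient="records"), indent=2))
        else:
            frame.to_csv(path, index=False)
    except OSError as exc:
        raise InputError(f"cannot write results to {path!s}: {exc}") from exc


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a measurement table written by :func:`write_measurements`."""
    path = Path(path)
    try:
        if path.suffix.lower() == ".json":
            frame = pd.DataFrame(json.loads(path.read_text()))
        else:
            frame = pd.read_csv(path, keep_default_na=False)
    except OSError as exc:
        raise InputError(f"cannot read results from {path!s}: {exc}") from exc
    return frame[list(MEASUREMENT_COLUMNS)]
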