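"""Deterministic segmentation of the rib-eye and its marbling.

This module replaces an interactive grayscale/contrast/threshold/particle
workflow with programmatic equivalents:

* 8-bit grayscale conversion (unweighted channel mean by default, luma
  weights by flag),
* percentile auto-contrast (linear stretch with a small saturated
  fraction at each histogram tail),
* isodata (intermeans) automatic thresholding,
* connected-component "particle" analysis with a calibrated size filter.

The rib-eye itself is the bright object on a dark matte background; its
marbling (intramuscular fat) is the bright class *within* the rib-eye mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure

from .config import PipelineConfig
from .errors import DegenerateHistogramError, SegmentationError
from .io_calibration import CalibratedImage, RGBImage, ScaleCalibration, cm2_to_px2, px2_to_cm2

__all__ = [
    "GrayImage",
    "BinaryMask",
    "Particle",
    "to_grayscale",
    "auto_contrast",
    "histogram256",
    "isodata_threshold",
    "intermeans_fixed_points",
    "segment_ribeye",
    "segment_marbling",
    "particle_analysis",
    "crop_to_mask",
]


@dataclass
class GrayImage:
    """An 8-bit single-channel raster plus the conversion mode that made it."""

    pixels: np.ndarray
    mode: str = "unweighted"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise SegmentationError(f"grayscale image must be 2-D, got shape {px.shape}")
        self.pixels = px.astype(np.uint8, copy=False)


@dataclass
class BinaryMask:
    """A boolean object mask (True = object) with a role tag."""

    pixels: np.ndarray
    role: str = "ribeye"
    warnings: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class Particle:
    """One 8-connected component surviving the size filter."""

    area_px: int
    area_cm2: float
    centroid: tuple[float, float]  # (x, y) pixel coordinates
    bbox: tuple[int, int, int, int]  # (x_min, y_min, x_max, y_max), inclusive


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # numpy rounds halves to even; the classic image-processing convention
    # (and the one all worked examples here assume) is half-up.
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


def to_grayscale(img: RGBImage, mode: str = "unweighted") -> GrayImage:
    """Convert RGB to 8-bit grayscale.

    ``unweighted``: g = round((R + G + B) / 3).
    ``luma``:       g = round(0.299 R + 0.587 G + 0.114 B).
    """
    px = img.pixels.astype(np.float64)
    if mode == "unweighted":
        g = px.sum(axis=2) / 3.0
    elif mode == "luma":
        g = px[:, :, 0] * 0.299 + px[:, :, 1] * 0.587 + px[:, :, 2] * 0.114
    else:
        raise ValueError(f"unknown grayscale mode {mode!r}")
    g = np.clip(_round_half_up(g), 0, 255).astype(np.uint8)
    return GrayImage(pixels=g, mode=mode)


def histogram256(pixels: np.ndarray) -> np.ndarray:
    """256-bin intensity histogram of an 8-bit array (any shape)."""
    return np.bincount(np.asarray(pixels, dtype=np.uint8).ravel(), minlength=256)


def auto_contrast(gray: GrayImage, saturated_fraction: float = 0.0035) -> GrayImage:
    """Linear contrast stretch with tail saturation.

    Cut intensities are chosen from the 256-bin histogram so that at most
    ``saturated_fraction / 2`` of the pixels lie below the low cut and above
    the high cut; the range [low, high] is then mapped linearly onto
    [0, 255] with clamping.  A degenerate histogram (low == high) returns
    the input unchanged.
    """
    if not 0.0 <= saturated_fraction < 0.5:
        raise ValueError("saturated_fraction must lie in [0, 0.5)")
    px = gray.pixels
    n = px.size
    k = int(n * saturated_fraction / 2.0)
    csum = np.cumsum(histogram256(px))
    low = int(np.searchsorted(csum, k + 1))  # value of the (k+1)-th smallest pixel
    high = int(np.searchsorted(csum, n - k))  # value of the (k+1)-th largest pixel
    if low == high:
        return GrayImage(pixels=px.copy(), mode=gray.mode)
    scaled = (px.astype(np.float64) - low) * (255.0 / (high - low))
    out = np.clip(_round_half_up(scaled), 0, 255).astype(np.uint8)
    return GrayImage(pixels=out, mode=gray.mode)


def _class_means(hist: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative means of the classes (<= t) and (> t) for every t in 0..255."""
    hist = hist.astype(np.float64)
    vals = np.arange(256, dtype=np.float64)
    cnt_lo = np.cumsum(hist)
    sum_lo = np.cumsum(hist * vals)
    cnt_hi = cnt_lo[-1] - cnt_lo
    sum_hi = sum_lo[-1] - sum_lo
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_lo = np.where(cnt_lo > 0, sum_lo / cnt_lo, np.nan)
        mean_hi = np.where(cnt_hi > 0, sum_hi / cnt_hi, np.nan)
    return mean_lo, mean_hi


def _as_histogram(gray_or_hist) -> np.ndarray:
    if isinstance(gray_or_hist, GrayImage):
        return histogram256(gray_or_hist.pixels)
    arr = np.asarray(gray_or_hist)
    if arr.ndim == 1 and arr.size == 256:
        return arr
    return histogram256(arr)


def isodata_threshold(gray_or_hist, start: int | None = None) -> int:
    """Isodata (intermeans) automatic threshold on a 256-bin histogram.

    Starting from the mid-intensity of the populated range (or ``start``),
    iterate t <- round((mean(values <= t) + mean(values > t)) / 2) to a
    fixed point.  Object pixels for a bright-on-dark scene are those
    strictly above the returned threshold.

    Raises :class:`DegenerateHistogramError` for a single-valued image.
    """
    hist = _as_histogram(gray_or_hist)
    populated = np.flatnonzero(hist)
    if populated.size < 2:
        raise DegenerateHistogramError("histogram has fewer than 2 populated bins")
    lo, hi = int(populated[0]), int(populated[-1])
    mean_lo, mean_hi = _class_means(hist)

    def clamp(t: int) -> int:
        return max(lo, min(hi - 1, t))

    t = clamp((lo + hi) // 2 if start is None else int(start))
    seen: set[int] = set()
    while t not in seen:
        seen.add(t)
        t = clamp(int(np.floor((mean_lo[t] + mean_hi[t]) / 2.0 + 0.5)))
    return t


def intermeans_fixed_points(gray_or_hist) -> list[int]:
    """All thresholds t satisfying t == round((mean(<=t) + mean(>t)) / 2).

    A multi-modal histogram (dark background, mid-gray muscle, bright fat)
    can have several intermeans fixed points, one per pairwise mode split;
    the smallest separates the background from everything else.
    """
    hist = _as_histogram(gray_or_hist)
    populated = np.flatnonzero(hist)
    if populated.size < 2:
        raise DegenerateHistogramError("histogram has fewer than 2 populated bins")
    lo, hi = int(populated[0]), int(populated[-1])
    mean_lo, mean_hi = _class_means(hist)
    ts = np.arange(lo, hi)
    target = np.floor((mean_lo[ts] + mean_hi[ts]) / 2.0 + 0.5).astype(int)
    return [int(t) for t in ts[target == ts]]


def _preprocessed_gray(ci: CalibratedImage, config: PipelineConfig) -> GrayImage:
    gray = to_grayscale(ci.image, mode=config["grayscale.mode"])
    return auto_contrast(gray, saturated_fraction=config["autocontrast.saturation"])


def _ribeye_threshold(gray: GrayImage, config: PipelineConfig) -> int:
    if config["threshold.method"] == "fixed":
        value = config["threshold.fixed_value"]
        if value is None:
            raise SegmentationError("threshold.method=fixed requires threshold.fixed_value")
        return int(value)
    # Background/foreground split: the smallest intermeans fixed point.  With
    # heavy marbling the histogram is trimodal (background, muscle, fat) and
    # the plain mid-start iteration can converge onto the muscle/fat split,
    # which would classify lean muscle as background.
    fixed = intermeans_fixed_points(gray)
    return fixed[0] if fixed else isodata_threshold(gray)


def segment_ribeye(ci: CalibratedImage, config: PipelineConfig | None = None) -> BinaryMask:
    """Segment the rib-eye muscle (including its marbling) from the background.

    Pipeline: grayscale -> auto-contrast -> automatic threshold (object =
    above threshold) -> fill internal holes -> drop components smaller than
    ``cleanup.min_object_cm2`` -> keep the largest 8-connected component.
    """
    config = PipelineConfig.ensure(config)
    gray = _preprocessed_gray(ci, config)
    try:
        t = _ribeye_threshold(gray, config)
    except DegenerateHistogramError as exc:
        raise SegmentationError(f"cannot threshold image: {exc}") from exc
    fg = gray.pixels > t
    fg = ndimage.binary_fill_holes(fg)  # 4-connected background convention
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise SegmentationError("no foreground object found after thresholding")
    min_px = cm2_to_px2(config["cleanup.min_object_cm2"], ci.calibration)
    counts = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(counts >= min_px) + 1
    if keep.size == 0:
        raise SegmentationError("all foreground components smaller than cleanup.min_object_cm2")
    largest = keep[np.argmax(counts[keep - 1])]
    return BinaryMask(pixels=labels == largest, role="ribeye")


def segment_marbling(
    ci: CalibratedImage, ribeye: BinaryMask, config: PipelineConfig | None = None
) -> BinaryMask:
    """Segment intramuscular fat within the rib-eye mask.

    Isodata thresholding is applied to the histogram of (contrast-adjusted)
    grayscale values restricted to the rib-eye; fat is the brighter class.
    If the split separates the within-mask intensities by less than
    ``marbling.min_separation`` gray levels, the sample is treated as
    uniform lean: an empty mask is returned with a warning flag rather than
    an arbitrary split of sensor noise.
    """
    config = PipelineConfig.ensure(config)
    if ribeye.area_px == 0:
        raise SegmentationError("ribeye mask is empty")
    gray = _preprocessed_gray(ci, config)
    inside = gray.pixels[ribeye.pixels]
    hist = histogram256(inside)
    warnings: tuple[str, ...] = ()
    try:
        t = isodata_threshold(hist)
    except DegenerateHistogramError:
        return BinaryMask(
            pixels=np.zeros(ribeye.shape, dtype=bool),
            role="marbling",
            warnings=("degenerate_within_mask_histogram",),
        )
    mean_lo, mean_hi = _class_means(hist)
    if mean_hi[t] - mean_lo[t] < config["marbling.min_separation"]:
        return BinaryMask(
            pixels=np.zeros(ribeye.shape, dtype=bool),
            role="marbling",
            warnings=("no_separable_fat_class",),
        )
    fat = (gray.pixels > t) & ribeye.pixels
    return BinaryMask(pixels=fat, role="marbling", warnings=warnings)


def particle_analysis(
    mask: BinaryMask,
    cal: ScaleCalibration,
    min_size_cm2: float = 0.5,
    max_size_cm2: float = np.inf,
) -> list[Particle]:
    """Label 8-connected components and filter them by calibrated area.

    Components with area outside [min_size_cm2, max_size_cm2] are
    discarded; survivors are sorted by area descending, ties broken by
    centroid (y, x).  An empty mask yields an empty list.
    """
    labels, n = ndimage.label(mask.pixels, structure=np.ones((3, 3), dtype=int))
    particles: list[Particle] = []
    for region in skmeasure.regionprops(labels):
        area_cm2 = px2_to_cm2(region.area, cal)
        if area_cm2 < min_size_cm2 or area_cm2 > max_size_cm2:
            continue
        cy, cx = region.centroid
        r0, c0, r1, c1 = region.bbox  # half-open rows/cols
        particles.append(
            Particle(
                area_px=int(region.area),
                area_cm2=area_cm2,
                centroid=(float(cx), float(cy)),
                bbox=(int(c0), int(r0), int(c1 - 1), int(r1 - 1)),
            )
        )
    particles.sort(key=lambda p: (-p.area_px, p.centroid[1], p.centroid[0]))
    return particles


def crop_to_mask(
    ci: CalibratedImage, mask: BinaryMask, margin_px: int = 0
) -> tuple[CalibratedImage, BinaryMask]:
    """Crop image and mask to the mask's bounding box plus a margin.

    The margin is clamped to the frame; calibration is unchanged, so all
    calibrated measurements are invariant to the crop.
    """
    if margin_px < 0:
        raise ValueError("margin_px must be >= 0")
    if mask.area_px == 0:
        raise SegmentationError("cannot crop to an empty mask")
    rows = np.flatnonzero(mask.pixels.any(axis=1))
    cols = np.flatnonzero(mask.pixels.any(axis=0))
    h, w = mask.shape
    r0, r1 = max(0, rows[0] - margin_px), min(h, rows[-1] + 1 + margin_px)
    c0, c1 = max(0, cols[0] - margin_px), min(w, cols[-1] + 1 + margin_px)
    cropped_img = RGBImage(
        pixels=ci.image.pixels[r0:r1, c0:c1].copy(),
        source=ci.image.source,
        colorspace=ci.image.colorspace,
    )
    cropped_mask = BinaryMask(
        pixels=mask.pixels[r0:r1, c0:c1].copy(), role=mask.role, warnings=mask.warnings
    )
    return CalibratedImage(image=cropped_img, calibration=ci.calibration), cropped_mask
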