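"""Synthetic rib-eye images with exact ground truth.

Real graded rib-eye photographs are rarely shareable, so every stage of
the pipeline is exercised against generated scenes instead: a smooth,
mildly perturbed elliptical muscle silhouette on a near-black matte
background, an internal network of fat blobs realised at a controlled area
fraction, grade-typical muscle/fat palettes, Gaussian sensor noise, and an
embedded scale bar of known physical length.  The rendering stencils *are*
the ground truth — masks, area, marbling fraction and channel statistics
are computed from them exactly, before noise.

Silhouette sizes default to the commercial sampling range the pipeline is
meant for (cross-section length about 8-15 cm, width 5-10 cm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

from .errors import GenerationError
from .grading import GRADE_LABELS, GradingTable, default_grading_table, grade_parameter
from .io_calibration import CalibratedImage, RGBImage, calibrate_scale
from .measurement import measure_dimensions
from .segmentation import BinaryMask

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_sample",
    "generate_grade_panel",
    "render_scale_bar",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic rib-eye scene."""

    seed: int
    px_per_cm: float = 20.0
    semi_axes_cm: tuple[float, float] = (5.5, 3.6)
    boundary_amplitude: float = 0.06
    orientation_deg: float = 0.0
    target_marbling_fraction: float = 0.25
    blob_size_range_cm2: tuple[float, float] = (0.8, 3.0)
    max_fat_blobs: int = 800
    muscle_rgb: tuple[int, int, int] = (150, 60, 55)
    fat_rgb: tuple[int, int, int] = (235, 228, 218)
    background_rgb: tuple[int, int, int] = (10, 10, 10)
    noise_sd: float = 3.0
    scale_bar_cm: float = 5.0
    scale_bar_angle_deg: float = 0.0
    margin_cm: float = 0.8
    intended_grade: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_marbling_fraction < 1.0:
            raise GenerationError("target_marbling_fraction must lie in [0, 1)")
        if min(self.semi_axes_cm) <= 0 or self.px_per_cm <= 0:
            raise GenerationError("silhouette axes and px_per_cm must be positive")


@dataclass
class GroundTruth:
    """Exact per-sample truth computed from the rendering stencils."""

    ribeye_mask: BinaryMask
    marbling_mask: BinaryMask
    area_cm2: float
    length_cm: float
    width_cm: float
    marbling_pct: float
    mean_r: float
    mean_g: float
    mean_b: float
    red_ratio: float
    intended_grade: str | None = None


def _frame_geometry(spec: SyntheticSpec) -> tuple[int, int, float, float, float]:
    ppc = spec.px_per_cm
    reach = max(spec.semi_axes_cm) * (1.0 + 2.0 * spec.boundary_amplitude)
    bar_strip_cm = 1.2 + spec.scale_bar_cm * abs(math.sin(math.radians(spec.scale_bar_angle_deg)))
    width_cm = max(2 * reach + 2 * spec.margin_cm, spec.scale_bar_cm + 2 * spec.margin_cm)
    height_cm = 2 * reach + 2 * spec.margin_cm + bar_strip_cm
    w = int(math.ceil(width_cm * ppc))
    h = int(math.ceil(height_cm * ppc))
    cx = w / 2.0
    cy = (spec.margin_cm + reach) * ppc
    return h, w, cx, cy, bar_strip_cm


def _silhouette(spec: SyntheticSpec, shape: tuple[int, int], cx: float, cy: float,
                rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    ppc = spec.px_per_cm
    a_px = spec.semi_axes_cm[0] * ppc
    b_px = spec.semi_axes_cm[1] * ppc
    harmonics = np.arange(2, 7)
    # geometric decay keeps the total boundary perturbation below 2x amplitude
    amps = spec.boundary_amplitude * rng.uniform(0.0, 1.0, harmonics.size) * (
        0.5 ** (harmonics - 2)
    )
    phases = rng.uniform(0.0, 2 * np.pi, harmonics.size)
    yy, xx = np.mgrid[0:h, 0:w]
    th = math.radians(spec.orientation_deg)
    dx, dy = xx - cx, yy - cy
    u = dx * math.cos(th) + dy * math.sin(th)
    v = -dx * math.sin(th) + dy * math.cos(th)
    phi = np.arctan2(v, u)
    rho = np.hypot(u, v)
    r_ellipse = a_px * b_px / np.sqrt((b_px * np.cos(phi)) ** 2 + (a_px * np.sin(phi)) ** 2)
    perturb = 1.0 + sum(
        c * np.cos(k * phi + p) for c, k, p in zip(amps, harmonics, phases)
    )
    return rho <= r_ellipse * perturb


def _fill_fat(
    spec: SyntheticSpec, silhouette: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Union of random ellipses inside the silhouette hitting the target fraction."""
    target = spec.target_marbling_fraction
    if target == 0.0:
        return np.zeros_like(silhouette)
    ppc = spec.px_per_cm
    sil_area_px = int(silhouette.sum())
    sil_area_cm2 = sil_area_px / ppc**2
    blob_lo, blob_hi = spec.blob_size_range_cm2
    erode_px = max(1, int(round(0.25 * ppc)))
    core = ndimage.binary_erosion(silhouette, iterations=erode_px)
    pool = np.argwhere(core if core.any() else silhouette)
    for _ in range(60):  # bounded restarts
        fat = np.zeros_like(silhouette)
        frac = 0.0
        for _ in range(spec.max_fat_blobs):
            needed = target - frac
            if needed <= 0.002:
                break
            blob_cm2 = float(np.clip(needed * sil_area_cm2 / max(1.0 - frac, 0.2),
                                     blob_lo, blob_hi))
            aspect = rng.uniform(0.45, 0.95)
            ra = math.sqrt(blob_cm2 / (math.pi * aspect)) * ppc
            rb = ra * aspect
            cy, cx = pool[rng.integers(len(pool))]
            rot = rng.uniform(0.0, math.pi)
            rr, cc = draw_ellipse(cy, cx, ra, rb, shape=silhouette.shape, rotation=rot)
            fat[rr, cc] = True
            fat &= silhouette
            frac = fat.sum() / sil_area_px
        if abs(frac - target) <= 0.01:
            return fat
    raise GenerationError(
        f"could not realise marbling fraction {target:.3f} with blobs in "
        f"{spec.blob_size_range_cm2} cm^2"
    )


def render_scale_bar(
    pixels: np.ndarray, spec: SyntheticSpec, forbidden: np.ndarray | None = None
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Draw the high-contrast scale bar in place; return its exact endpoints.

    The endpoints are exact (floating-point) pixel coordinates a known
    ``spec.scale_bar_cm`` apart, suitable for feeding straight into scale
    calibration.  Raises :class:`GenerationError` if the bar would overlap
    ``forbidden`` (e.g. the silhouette) or leave the frame.
    """
    h, w = pixels.shape[:2]
    ppc = spec.px_per_cm
    length_px = spec.scale_bar_cm * ppc
    theta = math.radians(spec.scale_bar_angle_deg)
    strip_px = (1.2 + spec.scale_bar_cm * abs(math.sin(theta))) * ppc
    x0 = spec.margin_cm * ppc * 0.75
    y0 = h - strip_px + 0.55 * ppc  # near the top of the reserved bottom strip
    dy = length_px * math.sin(theta)
    if dy < 0:  # upward tilt: start at the strip bottom instead
        y0 = h - 0.55 * ppc
    p1 = (x0, y0)
    p2 = (x0 + length_px * math.cos(theta), y0 + dy)
    if not (0 <= p2[0] < w and 0 <= p2[1] < h):
        raise GenerationError("scale bar does not fit in the frame")
    half_t = max(1.0, 0.05 * ppc)
    nx, ny = -math.sin(theta), math.cos(theta)
    corners_x = np.array([p1[0] + nx * half_t, p2[0] + nx * half_t,
                          p2[0] - nx * half_t, p1[0] - nx * half_t])
    corners_y = np.array([p1[1] + ny * half_t, p2[1] + ny * half_t,
                          p2[1] - ny * half_t, p1[1] - ny * half_t])
    rr, cc = draw_polygon(corners_y, corners_x, shape=(h, w))
    if forbidden is not None and forbidden[rr, cc].any():
        raise GenerationError("scale bar placement overlaps the silhouette")
    pixels[rr, cc] = (250, 250, 250)
    return p1, p2


def generate_sample(spec: SyntheticSpec) -> tuple[CalibratedImage, GroundTruth]:
    """Render one synthetic scene; deterministic for a fixed spec.

    The realised within-silhouette fat fraction is within one percentage
    point of ``spec.target_marbling_fraction`` (or generation fails after a
    bounded number of attempts).  Ground truth is computed from the clean
    stencils before noise is added.
    """
    rng = np.random.default_rng(spec.seed)
    h, w, cx, cy, _ = _frame_geometry(spec)
    silhouette = _silhouette(spec, (h, w), cx, cy, rng)
    if not silhouette.any():
        raise GenerationError("silhouette fell outside the frame")
    fat = _fill_fat(spec, silhouette, rng)

    pixels = np.empty((h, w, 3), dtype=np.float64)
    pixels[:] = spec.background_rgb
    pixels[silhouette] = spec.muscle_rgb
    pixels[fat] = spec.fat_rgb
    p1, p2 = render_scale_bar(pixels, spec, forbidden=silhouette)

    if spec.noise_sd > 0:
        pixels = pixels + rng.normal(0.0, spec.noise_sd, pixels.shape)
    pixels = np.clip(np.floor(pixels + 0.5), 0, 255).astype(np.uint8)

    calibration = calibrate_scale(p1, p2, spec.scale_bar_cm)
    image = RGBImage(pixels=pixels, source=f"synthetic:seed={spec.seed}")
    ci = CalibratedImage(image=image, calibration=calibration)

    ribeye_mask = BinaryMask(pixels=silhouette, role="ribeye")
    marbling_mask = BinaryMask(pixels=fat, role="marbling")
    n_total = int(silhouette.sum())
    n_fat = int(fat.sum())
    n_muscle = n_total - n_fat
    means = (
        np.asarray(spec.fat_rgb, dtype=np.float64) * n_fat
        + np.asarray(spec.muscle_rgb, dtype=np.float64) * n_muscle
    ) / n_total
    length_cm, width_cm, area_cm2 = measure_dimensions(ribeye_mask, calibration)
    truth = GroundTruth(
        ribeye_mask=ribeye_mask,
        marbling_mask=marbling_mask,
        area_cm2=area_cm2,
        length_cm=length_cm,
        width_cm=width_cm,
        marbling_pct=100.0 * n_fat / n_total,
        mean_r=float(means[0]),
        mean_g=float(means[1]),
        mean_b=float(means[2]),
        red_ratio=float(means[0] / means.sum()),
        intended_grade=spec.intended_grade,
    )
    return ci, truth


# ---------------------------------------------------------------------------
# grade-targeted panels


def _solve_palette(
    ratio_target: float, fat_fraction: float, grade_index: int
) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
    """Choose muscle/fat colors whose pixel mixture hits a target red ratio.

    Muscle brightness rises with grade (dark red A1 -> bright red A5), fat
    stays bright and near-neutral; the muscle red share is solved from the
    mixture equation for the realised fat fraction.  Palettes keep at least
    ~40 gray levels between fat and muscle so thresholding can separate
    the classes.
    """
    s_muscle = 170.0 + (grade_index - 1) / 4.0 * (400.0 - 170.0)
    s_fat = 600.0
    rho_f = float(np.clip(ratio_target - 0.02, 0.345, 0.40))
    rho_m = ratio_target
    for _ in range(60):
        denom = (1.0 - fat_fraction) * s_muscle
        if denom <= 1e-9:
            rho_f = float(np.clip(ratio_target, 0.34, 0.42))
            rho_m = 0.5
            break
        rho_m = (ratio_target * (fat_fraction * s_fat + denom)
                 - fat_fraction * rho_f * s_fat) / denom
        if rho_m > 0.64 and rho_f < 0.42:
            rho_f = min(rho_f + 0.01, 0.42)
        elif rho_m < 0.34 and rho_f > 0.30:
            rho_f = max(rho_f - 0.01, 0.30)
        else:
            break
    rho_m = float(np.clip(rho_m, 0.30, 0.66))

    def channels(total: float, red_share: float, g_frac: float) -> tuple[int, int, int]:
        r = red_share * total
        rest = total - r
        return (
            int(np.clip(round(r), 0, 255)),
            int(np.clip(round(rest * g_frac), 0, 255)),
            int(np.clip(round(rest * (1 - g_frac)), 0, 255)),
        )

    fat_rgb = channels(s_fat, rho_f, 0.53)
    muscle_rgb = channels(s_muscle, rho_m, 0.55)

    def mixture_ratio(m: tuple[int, int, int], f: tuple[int, int, int]) -> float:
        r = fat_fraction * f[0] + (1 - fat_fraction) * m[0]
        total = fat_fraction * sum(f) + (1 - fat_fraction) * sum(m)
        return r / total

    # nudge the integer muscle red channel to undo quantisation error
    best = muscle_rgb
    best_err = abs(mixture_ratio(best, fat_rgb) - ratio_target)
    for dr in range(-4, 5):
        cand = (int(np.clip(muscle_rgb[0] + dr, 0, 255)), muscle_rgb[1], muscle_rgb[2])
        err = abs(mixture_ratio(cand, fat_rgb) - ratio_target)
        if err < best_err:
            best, best_err = cand, err
    return best, fat_rgb


def _sampling_window(
    table: GradingTable, parameter: str, grade_index: int
) -> tuple[float, float]:
    iv = table.intervals[parameter][grade_index - 1]
    lo, hi = iv.lo, iv.hi
    if parameter == "area_cm2":
        if not math.isfinite(hi):
            hi = lo + 25.0
        w = hi - lo
        return lo + 0.12 * w, hi - 0.12 * w
    if parameter == "marbling_pct":
        w = hi - lo
        margin = 0.1 * w + 1.0  # extra point absorbs the generator's +-1pp tolerance
        return lo + margin, min(hi - margin, 90.0)
    # red_ratio: decreasing parameter with open-ended extreme bins
    if hi >= 1.0:
        hi = lo + 0.05
    if lo <= 0.0:
        lo = hi - 0.05
    w = hi - lo
    return lo + 0.25 * w, hi - 0.25 * w


def generate_grade_panel(
    n_per_grade: int,
    seed: int,
    table: GradingTable | None = None,
) -> list[tuple[CalibratedImage, GroundTruth]]:
    """Generate ``5 * n_per_grade`` samples, each targeted inside one grade.

    For every grade A1..A5, specs are drawn whose ground-truth area,
    marbling fraction and palette-implied red ratio all fall strictly
    inside that grade's intervals (with a safety margin from every
    boundary), so grading the ground truth per parameter is unanimous.
    """
    if n_per_grade < 1:
        raise GenerationError("n_per_grade must be >= 1")
    table = table if table is not None else default_grading_table()
    rng = np.random.default_rng(seed)
    panel: list[tuple[CalibratedImage, GroundTruth]] = []
    for grade_index, label in enumerate(GRADE_LABELS, start=1):
        area_win = _sampling_window(table, "area_cm2", grade_index)
        marb_win = _sampling_window(table, "marbling_pct", grade_index)
        ratio_win = _sampling_window(table, "red_ratio", grade_index)
        for _ in range(n_per_grade):
            for _attempt in range(25):
                area_t = rng.uniform(*area_win)
                marbling_t = rng.uniform(*marb_win) / 100.0
                ratio_t = rng.uniform(*ratio_win)
                aspect = rng.uniform(0.55, 0.80)
                semi_a = math.sqrt(area_t / (math.pi * aspect))
                spec = SyntheticSpec(
                    seed=int(rng.integers(2**31)),
                    semi_axes_cm=(semi_a, semi_a * aspect),
                    orientation_deg=float(rng.uniform(0.0, 180.0)),
                    target_marbling_fraction=marbling_t,
                    intended_grade=label,
                )
                ci, truth = generate_sample(spec)
                # geometry is now fixed; re-solve the palette for the
                # realised fat fraction and re-render with the same seed
                muscle_rgb, fat_rgb = _solve_palette(
                    ratio_t, truth.marbling_pct / 100.0, grade_index
                )
                spec = replace(spec, muscle_rgb=muscle_rgb, fat_rgb=fat_rgb)
                ci, truth = generate_sample(spec)
                ok = (
                    grade_parameter(truth.area_cm2, "area_cm2", table) == grade_index
                    and grade_parameter(truth.marbling_pct, "marbling_pct", table)
                    == grade_index
                    and grade_parameter(truth.red_ratio, "red_ratio", table) == grade_index
                )
                if ok:
                    panel.append((ci, truth))
                    break
            else:
                raise GenerationError(
                    f"could not draw a {label} sample inside its grade intervals"
                )
    return panel
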