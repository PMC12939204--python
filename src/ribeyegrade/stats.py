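"""Validation statistics: grid-paper area, outlier filtering, agreement.

The manual reference methods behind the image pipeline are (a) caliper
length/width and (b) grid-paper area counting: lay the cut on paper ruled
with squares of side ``a`` cm, count fully covered cells (N1) and cells
more than half covered (N2), ignore the rest, and estimate

    S = (N1 + N2) * a^2.

This module computes that estimate, simulates the counting protocol on a
binary mask (so the manual method can serve as an oracle for synthetic
samples), removes gross outliers from repeated measurements via a Gaussian
fit, and quantifies method agreement with Pearson correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats

from .errors import StatsError
from .io_calibration import ScaleCalibration
from .segmentation import BinaryMask

__all__ = [
    "GridCount",
    "GaussianFit",
    "AgreementReport",
    "AccuracyReport",
    "grid_area",
    "simulate_grid_count",
    "gaussian_outlier_filter",
    "pearson_agreement",
    "agreement_by_parameter",
    "grading_accuracy",
]


@dataclass(frozen=True)
class GridCount:
    """Grid-paper counts: N1 fully covered cells, N2 majority-covered cells."""

    n1: int
    n2: int
    a_cm: float

    def __post_init__(self) -> None:
        if self.n1 < 0 or self.n2 < 0:
            raise StatsError("grid counts must be nonnegative")
        if self.a_cm <= 0:
            raise StatsError("grid side length must be positive")


@dataclass(frozen=True)
class GaussianFit:
    """Result of Gaussian outlier elimination on repeated measurements."""

    mu: float
    sigma: float
    n_used: int
    retained_indices: tuple[int, ...]


@dataclass(frozen=True)
class AgreementReport:
    """Pearson agreement between two measurement methods."""

    pearson_r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class AccuracyReport:
    """Classification accuracy with per-grade confusion counts."""

    percentage: float
    n_correct: int
    n_total: int
    confusion: dict[str, dict[str, int]]  # reference label -> predicted label -> count


def grid_area(gc: GridCount) -> float:
    """Grid-paper area estimate S = (N1 + N2) * a^2 in cm^2."""
    return (gc.n1 + gc.n2) * gc.a_cm**2


def _integral_image(mask: np.ndarray) -> np.ndarray:
    # F[i, j] = integral of the pixel-indicator function over [0, j] x [0, i];
    # the indicator is constant on unit pixel squares, so F is exactly
    # bilinear between grid points and fractional cell edges can be
    # evaluated exactly by bilinear interpolation.
    padded = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1), dtype=np.float64)
    padded[1:, 1:] = np.cumsum(np.cumsum(mask.astype(np.float64), axis=0), axis=1)
    return padded


def _eval_integral(F: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Bilinear (exact) evaluation of the integral image at fractional coords."""
    h, w = F.shape
    x = np.clip(np.asarray(x, dtype=np.float64), 0, w - 1)
    y = np.clip(np.asarray(y, dtype=np.float64), 0, h - 1)
    x0 = np.clip(np.floor(x).astype(int), 0, w - 2)
    y0 = np.clip(np.floor(y).astype(int), 0, h - 2)
    fx, fy = x - x0, y - y0
    return (
        F[y0, x0] * (1 - fx) * (1 - fy)
        + F[y0, x0 + 1] * fx * (1 - fy)
        + F[y0 + 1, x0] * (1 - fx) * fy
        + F[y0 + 1, x0 + 1] * fx * fy
    )


def simulate_grid_count(mask: BinaryMask, cal: ScaleCalibration, a_cm: float) -> GridCount:
    """Simulate the manual grid-paper counting protocol on a mask.

    An axis-aligned grid of side ``a_cm`` with its origin at the mask's
    bounding-box corner is overlaid; cell coverage is computed exactly
    (fractional pixel overlap included).  Fully covered cells count toward
    N1, cells with coverage strictly above one half toward N2, the rest are
    ignored.
    """
    if mask.area_px == 0:
        raise StatsError("cannot grid-count an empty mask")
    a_px = a_cm * cal.px_per_cm
    if a_px < 1.0:
        raise StatsError(f"grid side {a_cm} cm is below one pixel at this scale")
    rows = np.flatnonzero(mask.pixels.any(axis=1))
    cols = np.flatnonzero(mask.pixels.any(axis=0))
    y_origin, x_origin = float(rows[0]), float(cols[0])
    ny = int(math.ceil((rows[-1] + 1 - y_origin) / a_px))
    nx = int(math.ceil((cols[-1] + 1 - x_origin) / a_px))
    F = _integral_image(mask.pixels)
    xs = x_origin + np.arange(nx + 1) * a_px
    ys = y_origin + np.arange(ny + 1) * a_px
    X0, Y0 = np.meshgrid(xs[:-1], ys[:-1])
    X1, Y1 = np.meshgrid(xs[1:], ys[1:])
    covered = (
        _eval_integral(F, X1, Y1)
        - _eval_integral(F, X0, Y1)
        - _eval_integral(F, X1, Y0)
        + _eval_integral(F, X0, Y0)
    )
    coverage = covered / (a_px**2)
    n1 = int(np.count_nonzero(coverage >= 1.0 - 1e-9))
    n2 = int(np.count_nonzero((coverage > 0.5 + 1e-9) & (coverage < 1.0 - 1e-9)))
    return GridCount(n1=n1, n2=n2, a_cm=a_cm)


def gaussian_outlier_filter(
    values: Sequence[float], k: float = 2.5, max_iter: int = 1
) -> GaussianFit:
    """Remove gross outliers under a fitted Gaussian, then refit.

    The location/scale are the maximum-likelihood estimates (sample mean
    and SD); values farther than ``k`` standard deviations from the mean
    are removed, and the fit is refreshed on the retained set (``max_iter``
    removal passes, default one).  Requires at least 4 values and nonzero
    spread.  Removing more than half the data aborts with an error — that
    signals pathological input, not random outliers.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 1 or arr.size < 4:
        raise StatsError("need at least 4 values for outlier filtering")
    if k <= 0:
        raise StatsError("k must be positive")
    retained = np.arange(arr.size)
    for _ in range(max_iter):
        sub = arr[retained]
        mu, sigma = float(sub.mean()), float(sub.std(ddof=0))
        if sigma == 0.0:
            raise StatsError("all values identical; Gaussian fit degenerate")
        keep = np.abs(sub - mu) <= k * sigma
        if keep.all():
            break
        retained = retained[keep]
        if retained.size < math.ceil(arr.size / 2):
            raise StatsError("outlier filter would remove more than half the data")
    sub = arr[retained]
    mu, sigma = float(sub.mean()), float(sub.std(ddof=0))
    if sigma == 0.0:
        raise StatsError("retained values identical; Gaussian fit degenerate")
    return GaussianFit(
        mu=mu, sigma=sigma, n_used=int(retained.size), retained_indices=tuple(int(i) for i in retained)
    )


def pearson_agreement(x: Sequence[float], y: Sequence[float]) -> AgreementReport:
    """Product-moment correlation with a two-sided t-test p-value (df = n - 2)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("x and y must be 1-D sequences of equal length")
    if x.size < 3:
        raise StatsError("need at least 3 paired values")
    if x.std() == 0.0 or y.std() == 0.0:
        raise StatsError("zero variance in one of the inputs")
    result = scipy_stats.pearsonr(x, y)
    p = max(float(result.pvalue), float(np.finfo(np.float64).tiny))
    return AgreementReport(pearson_r=float(result.statistic), p_value=p, n=int(x.size))


def agreement_by_parameter(
    image_df: pd.DataFrame,
    manual_df: pd.DataFrame,
    parameters: Sequence[str] = ("length_cm", "width_cm", "area_cm2"),
    key: str = "sample_id",
) -> dict[str, AgreementReport]:
    """Per-parameter agreement between two measurement tables keyed by sample.

    Both frames must share at least 3 ``sample_id`` values and contain the
    requested parameter columns.
    """
    merged = image_df.merge(manual_df, on=key, suffixes=("_image", "_manual"))
    if len(merged) < 3:
        raise StatsError(f"need at least 3 shared {key} values, got {len(merged)}")
    reports = {}
    for param in parameters:
        reports[param] = pearson_agreement(
            merged[f"{param}_image"].to_numpy(), merged[f"{param}_manual"].to_numpy()
        )
    return reports


def grading_accuracy(
    predicted: Sequence[str], reference: Sequence[str]
) -> AccuracyReport:
    """Percentage of samples graded identically to the reference labels."""
    predicted, reference = list(predicted), list(reference)
    if len(predicted) != len(reference):
        raise StatsError("predicted and reference label lists differ in length")
    if not predicted:
        raise StatsError("cannot compute accuracy of an empty label list")
    confusion: dict[str, dict[str, int]] = {}
    n_correct = 0
    for pred, ref in zip(predicted, reference):
        confusion.setdefault(str(ref), {}).setdefault(str(pred), 0)
        confusion[str(ref)][str(pred)] += 1
        n_correct += pred == ref
    return AccuracyReport(
        percentage=100.0 * n_correct / len(predicted),
        n_correct=n_correct,
        n_total=len(predicted),
        confusion=confusion,
    )
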