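"""Metric distance calibration, ROI measurement and depth-map entropy.

The refocus parameter alpha is linear in physical displacement along the
optical axis, so a depth map in alpha units is converted to millimetres by
a straight line ``mm = slope * alpha + intercept`` fitted on a staircase
target of known floor heights.  ROI statistics quantify measurement error
against reference heights; discrete entropy of the gray-level histogram
scores the foreground/background contrast of a depth map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .depth import RelativeDepthMap

__all__ = [
    "CalibrationFit",
    "MetricDepthMap",
    "RoiMeasurement",
    "fit_distance_calibration",
    "roi_representative",
    "to_metric",
    "measure_roi",
    "discrete_entropy",
]

Rect = tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open, 0-based


@dataclass(frozen=True)
class CalibrationFit:
    """Least-squares line mapping alpha units to millimetres."""

    slope: float  # mm per alpha unit
    intercept: float  # mm
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a calibration fit needs at least 2 points")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")

    def alpha_to_mm(self, alpha: np.ndarray | float) -> np.ndarray | float:
        return self.slope * alpha + self.intercept

    def mm_to_alpha(self, mm: np.ndarray | float) -> np.ndarray | float:
        return (mm - self.intercept) / self.slope


@dataclass
class MetricDepthMap:
    """Per-pixel depth in millimetres, carrying the fit that produced it."""

    depth_mm: np.ndarray
    provenance: CalibrationFit

    def __post_init__(self) -> None:
        self.depth_mm = np.asarray(self.depth_mm, dtype=np.float64)
        if not np.all(np.isfinite(self.depth_mm)):
            raise ValueError("metric depth must be finite")


@dataclass(frozen=True)
class RoiMeasurement:
    """Height statistics of a rectangular ROI against a reference height."""

    roi: Rect
    mean_height_mm: float
    mean_error_mm: float
    reference_mm: float


def fit_distance_calibration(
    pairs: list[tuple[float, float]], through_origin: bool = False
) -> CalibrationFit:
    """Fit ``mm = slope * alpha (+ intercept)`` to (alpha, known_mm) pairs.

    ``through_origin=True`` fits a single scale coefficient with no
    intercept, for strict single-coefficient replication.
    """
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] != 2:
        raise ValueError("need at least 2 (alpha, mm) pairs")
    a, mm = arr[:, 0], arr[:, 1]
    if np.ptp(a) == 0:
        raise ValueError("degenerate calibration: all alpha values are equal")
    if through_origin:
        slope = float(a @ mm / (a @ a))
        resid = mm - slope * a
        ss_tot = float(np.sum((mm - mm.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - float(resid @ resid) / ss_tot)
        return CalibrationFit(slope=slope, intercept=0.0, r_squared=min(r2, 1.0),
                              n_points=len(a))
    res = stats.linregress(a, mm)
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(a),
    )


def _roi_values(arr: np.ndarray, roi: Rect) -> np.ndarray:
    r0, c0, r1, c1 = roi
    h, w = arr.shape[:2]
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"ROI {roi} empty or outside a {h}x{w} map")
    return arr[r0:r1, c0:c1].ravel()


def roi_representative(
    depth: RelativeDepthMap | np.ndarray, roi: Rect, trim_fraction: float = 0.1
) -> float:
    """Trimmed mean (central 80 % by default) of the depth values in a ROI.

    Robust stand-in for 'a representative value close to the ROI average'
    in the presence of outlier pixels.
    """
    arr = depth.depth if isinstance(depth, RelativeDepthMap) else np.asarray(depth)
    vals = _roi_values(arr, roi)
    return float(stats.trim_mean(vals, trim_fraction))


def to_metric(depth: RelativeDepthMap, fit: CalibrationFit) -> MetricDepthMap:
    """Affine conversion of an alpha-unit map to millimetres."""
    return MetricDepthMap(depth_mm=fit.alpha_to_mm(depth.depth), provenance=fit)


def measure_roi(
    metric: MetricDepthMap, roi: Rect, reference_mm: float, baseline_mm: float = 0.0
) -> RoiMeasurement:
    """Mean height above ``baseline_mm`` in the ROI and mean |error| vs reference."""
    heights = _roi_values(metric.depth_mm, roi) - baseline_mm
    return RoiMeasurement(
        roi=roi,
        mean_height_mm=float(heights.mean()),
        mean_error_mm=float(np.abs(heights - reference_mm).mean()),
        reference_mm=reference_mm,
    )


def discrete_entropy(
    image: np.ndarray,
    levels: int = 256,
    value_range: tuple[float, float] | None = None,
) -> float:
    """Shannon entropy (bits) of the image's quantized gray-level histogram.

    Values are binned into ``levels`` equal bins over the image's own
    min-max range by default; pass ``value_range=(0, 255)`` for byte
    images with an absolute scale.  A constant image has zero entropy; the
    maximum is ``log2(levels)``.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    img = np.asarray(image, dtype=np.float64).ravel()
    if img.size == 0:
        raise ValueError("empty image")
    lo, hi = value_range if value_range is not None else (img.min(), img.max())
    if hi <= lo:
        return 0.0
    counts, _ = np.histogram(img, bins=levels, range=(lo, hi))
    p = counts[counts > 0] / img.size
    return float(-(p * np.log2(p)).sum())
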