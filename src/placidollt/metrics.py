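"""Placido-disk reflectivity metrics.

Twelve per-frame summaries of the processed pupil ROI.  The premise: a
thicker lipid layer reflects the projected rings with higher intensity, so
brightness- and contrast-type features of the grey-level histogram track
lipid layer thickness.  Dividing by the pixel count n makes every metric
comparable across ROI sizes.

With p a pixel grey value, n the ROI pixel count, pmax the maximum ROI
intensity and x the mean:

    energy           = sum(p^2) / n
    relative energy  = sum((p / pmax)^2) / n        (= energy / pmax^2)
    entropy          = Shannon entropy of the grey-level frequency
                       distribution, divided by n
    SD irregularity  = sum(((p - x) / pmax)^2) / n  (= var(p) / pmax^2)

plus mean, SD (population), median, mode, minimum, kurtosis and skewness of
the histogram, and the total area under the 2-D intensity surface divided
by n.  Metrics that are undefined on an ROI (pmax = 0, zero variance,
fewer than 4 grid points) are reported as NaN, never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .preprocess import ProcessedROI

__all__ = [
    "METRIC_NAMES",
    "MetricsConfig",
    "IntensityHistogram",
    "ReflectivityMetrics",
    "histogram",
    "energy",
    "relative_energy",
    "entropy",
    "sd_irregularity",
    "total_area",
    "basic_stats",
    "compute_all",
]

#: Canonical metric order used in every table this package writes.
METRIC_NAMES = (
    "total_area",
    "minimum",
    "energy",
    "relative_energy",
    "entropy",
    "sd_irregularity",
    "mean",
    "sd",
    "median",
    "mode",
    "kurtosis",
    "skewness",
)


@dataclass(frozen=True)
class MetricsConfig:
    """Interpretation switches for the under-specified metric details.

    entropy_log_base: 'e' (natural log, default) or a numeric base.
    entropy_mode: 'frequency' (Shannon entropy of the grey-level frequency
        distribution / n, default) or 'pixel' (literal -sum(p*log p)/n over
        pixel grey values).
    pmax_mode: 'roi' normalises by the per-ROI maximum (default); 'full'
        uses the fixed 8-bit ceiling 255.
    area_stage: intensity surface integrated 'post' (default) or 'pre'
        contrast enhancement.
    """

    entropy_log_base: float | str = "e"
    entropy_mode: str = "frequency"
    pmax_mode: str = "roi"
    area_stage: str = "post"

    def __post_init__(self):
        if self.entropy_mode not in ("frequency", "pixel"):
            raise ParameterError(f"unknown entropy_mode {self.entropy_mode!r}")
        if self.pmax_mode not in ("roi", "full"):
            raise ParameterError(f"unknown pmax_mode {self.pmax_mode!r}")
        if self.area_stage not in ("post", "pre"):
            raise ParameterError(f"unknown area_stage {self.area_stage!r}")


_DEFAULT = MetricsConfig()


@dataclass(frozen=True)
class IntensityHistogram:
    """Exact 256-bin grey-level counts of an ROI."""

    counts: np.ndarray
    n: int


def histogram(roi: ProcessedROI) -> IntensityHistogram:
    levels = np.clip(np.rint(roi.values), 0, 255).astype(np.int64)
    counts = np.bincount(levels, minlength=256)
    return IntensityHistogram(counts=counts, n=roi.n)


def _pmax(roi: ProcessedROI, config: MetricsConfig) -> float:
    return 255.0 if config.pmax_mode == "full" else roi.pmax


def energy(roi: ProcessedROI) -> float:
    """Mean squared intensity, sum(p^2)/n."""
    return float(np.mean(roi.values**2))


def relative_energy(roi: ProcessedROI, config: MetricsConfig = _DEFAULT) -> float:
    """Mean squared intensity normalised by pmax^2; 1 for a uniform ROI.

    NaN (undefined) on an all-black ROI.
    """
    pmax = _pmax(roi, config)
    if pmax == 0:
        return math.nan
    return float(np.mean((roi.values / pmax) ** 2))


def entropy(roi: ProcessedROI, config: MetricsConfig = _DEFAULT) -> float:
    """Grey-level randomness of the ROI, divided by n.

    Default reading: Shannon entropy of the grey-level relative-frequency
    distribution (zero-frequency bins contribute 0), natural log, divided by
    the pixel count so ROI sizes are comparable.  The 'pixel' mode instead
    evaluates -sum(p * log p)/n over the raw grey values.
    """
    log = math.log if config.entropy_log_base == "e" else None
    base = None if log else float(config.entropy_log_base)

    def _log(a: np.ndarray) -> np.ndarray:
        return np.log(a) if base is None else np.log(a) / math.log(base)

    if config.entropy_mode == "pixel":
        p = roi.values[roi.values > 0]
        return float(-np.sum(p * _log(p)) / roi.n)
    counts = histogram(roi).counts
    q = counts[counts > 0] / roi.n
    return float(-np.sum(q * _log(q)) / roi.n)


def sd_irregularity(roi: ProcessedROI, config: MetricsConfig = _DEFAULT) -> float:
    """Intensity variance scaled by pmax^2; 0 for a uniform ROI."""
    pmax = _pmax(roi, config)
    if pmax == 0:
        return math.nan
    x = roi.values.mean()
    return float(np.mean(((roi.values - x) / pmax) ** 2))


def total_area(roi: ProcessedROI, config: MetricsConfig = _DEFAULT) -> float:
    """Area under the 2-D intensity surface over the ROI bounding grid, / n.

    Composite trapezoidal integration (unit pixel spacing) over the bounding
    box of the mask; cells outside the mask are zero-imputed.  Undefined
    (NaN) when the grid has fewer than 2 points per axis.
    """
    if roi.n < 4:
        return math.nan
    grid = roi.grid_pre if (config.area_stage == "pre" and roi.grid_pre is not None) else roi.grid
    rows = np.flatnonzero(roi.mask.any(axis=1))
    cols = np.flatnonzero(roi.mask.any(axis=0))
    sub = grid[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]
    if sub.shape[0] < 2 or sub.shape[1] < 2:
        return math.nan
    area = np.trapezoid(np.trapezoid(sub, axis=1))
    return float(area / roi.n)


def basic_stats(roi: ProcessedROI) -> dict[str, float]:
    """Histogram summary statistics.

    mean; population SD; median (lower central order statistic for even n);
    mode (smallest grey level attaining the maximal count); minimum;
    Fisher-Pearson skewness g1 = m3/m2^1.5 and non-excess kurtosis
    g2 = m4/m2^2, both NaN on a zero-variance ROI.
    """
    v = roi.values
    n = v.size
    mean = float(v.mean())
    sd = float(v.std())
    median = float(np.sort(v)[(n - 1) // 2])
    counts = histogram(roi).counts
    mode = float(np.argmax(counts))
    minimum = float(v.min())
    if sd == 0:
        skew = kurt = math.nan
    else:
        d = v - mean
        m2 = float(np.mean(d**2))
        skew = float(np.mean(d**3)) / m2**1.5
        kurt = float(np.mean(d**4)) / m2**2
    return {
        "mean": mean,
        "sd": sd,
        "median": median,
        "mode": mode,
        "minimum": minimum,
        "skewness": skew,
        "kurtosis": kurt,
    }


@dataclass
class ReflectivityMetrics:
    """The twelve per-frame reflectivity metrics plus context."""

    total_area: float
    minimum: float
    energy: float
    relative_energy: float
    entropy: float
    sd_irregularity: float
    mean: float
    sd: float
    median: float
    mode: float
    kurtosis: float
    skewness: float
    t_after_blink: float = math.nan
    n: int = 0
    pmax: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES} | {
            "t_after_blink": self.t_after_blink,
            "n": self.n,
            "pmax": self.pmax,
        }

    def as_series(self) -> pd.Series:
        return pd.Series(self.as_dict())

    def __getitem__(self, name: str) -> float:
        if name not in METRIC_NAMES:
            raise KeyError(name)
        return getattr(self, name)


def compute_all(
    roi: ProcessedROI,
    t_after_blink: float = math.nan,
    config: MetricsConfig = _DEFAULT,
) -> ReflectivityMetrics:
    """Compute every metric; undefined ones are carried as NaN."""
    stats = basic_stats(roi)
    return ReflectivityMetrics(
        total_area=total_area(roi, config),
        minimum=stats["minimum"],
        energy=energy(roi),
        relative_energy=relative_energy(roi, config),
        entropy=entropy(roi, config),
        sd_irregularity=sd_irregularity(roi, config),
        mean=stats["mean"],
        sd=stats["sd"],
        median=stats["median"],
        mode=stats["mode"],
        kurtosis=stats["kurtosis"],
        skewness=stats["skewness"],
        t_after_blink=t_after_blink,
        n=roi.n,
        pmax=roi.pmax,
    )
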