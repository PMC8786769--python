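"""Cut-off based lipid layer thickness grading.

A metric value is turned into an LLT grade by sequential thresholding
against per-metric cut-offs.  Grades are 1 (open meshwork, thinnest),
2 (closed meshwork) and 3 denoting "3+" (wave and colour-fringe patterns
merged: grey-level analysis cannot separate them, that needs colour
information).  For most metrics higher values mean a thicker lipid layer;
kurtosis and skewness run the other way.

Ties at a cut-off are assigned to the thicker (healthier) grade, except in
binary screening, where a value exactly at the screening cut-off is called
normal -- both are the "tie goes upward" convention.

Cut-offs are cohort-, instrument- and pipeline-specific.  The shipped
default table carries the published reference values and is flagged
``reference_only``; recalibrate with :func:`calibrate_cutoffs` for any
deviation from the reference pipeline.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference
from .exceptions import CalibrationError, InputError
from .validation_stats import ROCResult, roc_analysis

__all__ = [
    "Direction",
    "MetricCutoffs",
    "CutoffTable",
    "default_cutoff_table",
    "classify_grade",
    "screen_altered",
    "calibrate_cutoffs",
]

#: Grade boundaries handled by calibration, in calibration order.
BOUNDARIES = ("screening", "grade_1_2", "grade_2_3")


class Direction(str, Enum):
    HIGHER_IS_THICKER = "higher_is_thicker"
    HIGHER_IS_THINNER = "higher_is_thinner"


@dataclass(frozen=True)
class MetricCutoffs:
    """Cut-offs of one metric: screening (1 vs >=2) and grade boundaries."""

    screening: float
    grade_1_2: float
    grade_2_3: float
    direction: Direction = Direction.HIGHER_IS_THICKER

    def ordered(self) -> bool:
        """Grade boundaries must move with the metric's direction."""
        if self.direction is Direction.HIGHER_IS_THICKER:
            return self.grade_1_2 <= self.grade_2_3
        return self.grade_2_3 <= self.grade_1_2


@dataclass
class CutoffTable:
    """Per-metric cut-offs and directions.

    ``reference_only`` marks tables whose thresholds come from published
    reference data rather than a calibration on the current pipeline.
    """

    cutoffs: dict[str, MetricCutoffs]
    source: str = ""
    reference_only: bool = False

    def __post_init__(self):
        bad = [m for m, c in self.cutoffs.items() if not c.ordered()]
        if bad:
            raise CalibrationError(f"grade boundaries out of order for: {', '.join(bad)}")

    def __contains__(self, metric: str) -> bool:
        return metric in self.cutoffs

    def __getitem__(self, metric: str) -> MetricCutoffs:
        try:
            return self.cutoffs[metric]
        except KeyError:
            raise CalibrationError(f"no cut-offs configured for metric {metric!r}") from None

    @property
    def metrics(self) -> tuple[str, ...]:
        return tuple(self.cutoffs)

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "reference_only": self.reference_only,
            "cutoffs": {
                m: {
                    "screening": c.screening,
                    "grade_1_2": c.grade_1_2,
                    "grade_2_3": c.grade_2_3,
                    "direction": c.direction.value,
                }
                for m, c in self.cutoffs.items()
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "CutoffTable":
        cutoffs = {
            m: MetricCutoffs(
                screening=c["screening"],
                grade_1_2=c["grade_1_2"],
                grade_2_3=c["grade_2_3"],
                direction=Direction(c["direction"]),
            )
            for m, c in d["cutoffs"].items()
        }
        return cls(cutoffs=cutoffs, source=d.get("source", ""), reference_only=d.get("reference_only", False))

    @classmethod
    def load(cls, path: str | Path) -> "CutoffTable":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_cutoff_table() -> CutoffTable:
    """The published reference cut-offs (5.33 s timepoint).

    Flagged ``reference_only``: instrument- and pipeline-specific;
    recalibrate for any deviation from the reference pipeline.
    """
    cutoffs = {
        m: MetricCutoffs(
            screening=reference.SCREENING[m].cutoff,
            grade_1_2=reference.GRADE_1_VS_2[m].cutoff,
            grade_2_3=reference.GRADE_2_VS_3[m].cutoff,
            direction=Direction(reference.DIRECTIONS[m]),
        )
        for m in reference.SCREENING
    }
    return CutoffTable(cutoffs=cutoffs, source=reference.REFERENCE_NOTE, reference_only=True)


def classify_grade(value: float, metric: str, cutoffs: CutoffTable) -> int | None:
    """Sequential thresholding of one metric value into grade 1, 2 or 3+.

    Missing values (NaN) yield a missing grade (None).  Boundary ties go to
    the thicker grade.
    """
    c = cutoffs[metric]
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if c.direction is Direction.HIGHER_IS_THICKER:
        if value < c.grade_1_2:
            return 1
        if value < c.grade_2_3:
            return 2
        return 3
    # higher_is_thinner: large values -> thin lipid layer
    if value > c.grade_1_2:
        return 1
    if value > c.grade_2_3:
        return 2
    return 3


def screen_altered(value: float, metric: str, cutoffs: CutoffTable) -> bool | None:
    """True when the value falls on the altered (grade 1) side of the
    screening cut-off; exact ties are called normal."""
    c = cutoffs[metric]
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if c.direction is Direction.HIGHER_IS_THICKER:
        return value < c.screening
    return value > c.screening


def calibrate_cutoffs(
    values: pd.DataFrame,
    grades,
    *,
    metrics: tuple[str, ...] | None = None,
    n_boot: int = 2000,
    seed: int = 0,
    strict: bool = True,
) -> tuple[CutoffTable, dict[str, dict[str, ROCResult]]]:
    """Recalibrate per-metric cut-offs from a cohort.

    ``values``: DataFrame with one row per subject and one column per
    metric.  ``grades``: subjective labels 1-4 (3 and 4 are merged to 3+).
    For each metric, three ROC analyses yield Youden-optimal thresholds:
    screening (1 vs >= 2), grade 1 vs 2, and grade 2 vs 3+.  The direction is
    inferred from the group means of the screening contrast.

    Returns the calibrated table and the per-metric, per-boundary ROC
    results.  With ``strict=False`` a metric whose fitted boundaries come
    out of order is dropped with a warning instead of raising.
    """
    grades = np.asarray(grades, dtype=int)
    if len(values) != len(grades):
        raise InputError("values and grades must have equal length")
    merged = np.minimum(grades, 3)
    use_metrics = tuple(metrics) if metrics is not None else tuple(values.columns)

    contrasts = {
        "screening": (np.ones_like(merged, dtype=bool), merged == 1),
        "grade_1_2": (np.isin(merged, (1, 2)), merged == 1),
        "grade_2_3": (np.isin(merged, (2, 3)), merged == 2),
    }
    for name, (subset, positive) in contrasts.items():
        if positive[subset].all() or not positive[subset].any():
            raise CalibrationError(f"boundary {name!r} has an empty side")

    table: dict[str, MetricCutoffs] = {}
    rocs: dict[str, dict[str, ROCResult]] = {}
    rng = np.random.default_rng(seed)
    for metric in use_metrics:
        v = values[metric].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        per_boundary: dict[str, ROCResult] = {}
        # thin (positive) group on the lower side => higher values mean thicker
        direction = None
        for name, (subset, positive) in contrasts.items():
            m = subset & ok
            res = roc_analysis(
                v[m],
                positive[m].astype(int),
                positive=1,
                n_boot=n_boot,
                seed=int(rng.integers(2**31)),
            )
            per_boundary[name] = res
            if name == "screening":
                direction = (
                    Direction.HIGHER_IS_THINNER
                    if res.direction == "higher"
                    else Direction.HIGHER_IS_THICKER
                )
        rocs[metric] = per_boundary
        cut = MetricCutoffs(
            screening=per_boundary["screening"].cutoff,
            grade_1_2=per_boundary["grade_1_2"].cutoff,
            grade_2_3=per_boundary["grade_2_3"].cutoff,
            direction=direction,
        )
        if not cut.ordered():
            if strict:
                raise CalibrationError(
                    f"calibrated boundaries for {metric!r} are out of order "
                    f"(1|2 = {cut.grade_1_2:g}, 2|3 = {cut.grade_2_3:g})"
                )
            warnings.warn(f"dropping metric {metric!r}: boundaries out of order", stacklevel=2)
            continue
        table[metric] = cut
    return CutoffTable(cutoffs=table, source="calibrated", reference_only=False), rocs
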