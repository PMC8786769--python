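"""Published reference values for the Keratograph 5M grading method.

These numbers were derived from a 94-subject clinical cohort (metrics at
5.33 s after blinking, the best-performing timepoint) on the reference
instrument and preprocessing chain.  They are design references: the
underlying recordings are not deposited, so none of these values can be
recomputed from data, and they are instrument- and pipeline-specific --
recalibrate (``grading.calibrate_cutoffs``) for any deviation from the
reference pipeline.  ``reference_only`` flags carry that warning into code.

Each boundary table maps metric name -> DiagnosticRow.  Boundaries:

* SCREENING      : altered (grade 1) vs normal (grades >= 2)
* GRADE_1_VS_2   : grade 1 vs grade 2
* GRADE_2_VS_3   : grade 2 vs grade 3+ (grades 3 and 4 merged; grey-level
                   analysis cannot separate them)
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType

__all__ = [
    "DiagnosticRow",
    "SCREENING",
    "GRADE_1_VS_2",
    "GRADE_2_VS_3",
    "AGREEMENT",
    "DIRECTIONS",
    "REFERENCE_ONLY",
    "REFERENCE_NOTE",
]

REFERENCE_ONLY = True

REFERENCE_NOTE = (
    "Reference diagnostic statistics from a 94-subject clinical cohort on the "
    "Oculus Keratograph 5M (metrics at 5.33 s after blinking). The recordings "
    "are not deposited, so these values are design references, not "
    "recomputable targets, and the cut-offs are instrument- and "
    "pipeline-specific: recalibrate for any deviation from the reference "
    "pipeline."
)


@dataclass(frozen=True)
class DiagnosticRow:
    """One metric's published diagnostic summary for one grade boundary."""

    sensitivity: float
    specificity: float
    auc: float
    auc_ci: tuple[float, float]
    cutoff: float
    youden: float
    discriminant_power: float


def _rows(data: dict[str, tuple]) -> MappingProxyType:
    return MappingProxyType(
        {name: DiagnosticRow(se, sp, auc, ci, cut, j, dp) for name, (se, sp, auc, ci, cut, j, dp) in data.items()}
    )


# Altered (grade 1) vs normal (>= 2)
SCREENING = _rows(
    {
        "total_area": (0.94, 0.76, 0.89, (0.83, 0.96), 117.74, 0.70, 2.18),
        "minimum": (0.92, 0.74, 0.88, (0.82, 0.95), 67.50, 0.65, 1.89),
        "energy": (0.87, 0.77, 0.82, (0.71, 0.88), 239.15, 0.65, 1.77),
        "relative_energy": (0.92, 0.81, 0.91, (0.83, 0.96), 0.48, 0.73, 2.13),
        "sd_irregularity": (0.89, 0.77, 0.86, (0.79, 0.94), 0.05, 0.66, 1.83),
        "mean": (0.94, 0.79, 0.89, (0.83, 0.96), 128.62, 0.74, 2.29),
        "sd": (0.83, 0.70, 0.78, (0.68, 0.88), 28.08, 0.53, 1.35),
        "median": (0.92, 0.81, 0.91, (0.84, 0.97), 124.50, 0.73, 2.13),
        "mode": (0.83, 0.77, 0.87, (0.80, 0.94), 133.50, 0.61, 1.56),
        "kurtosis": (0.89, 0.76, 0.83, (0.74, 0.92), 0.015, 0.64, 1.77),
        "skewness": (0.92, 0.72, 0.84, (0.75, 0.92), 0.13, 0.63, 1.84),
    }
)

GRADE_1_VS_2 = _rows(
    {
        "total_area": (0.89, 0.70, 0.83, (0.73, 0.94), 116.20, 0.59, 1.62),
        "minimum": (0.86, 0.74, 0.86, (0.77, 0.95), 64.50, 0.60, 1.58),
        "energy": (0.86, 0.73, 0.81, (0.71, 0.91), 238.59, 0.59, 1.55),
        "relative_energy": (0.92, 0.74, 0.83, (0.72, 0.94), 0.48, 0.66, 1.90),
        "sd_irregularity": (0.83, 0.70, 0.78, (0.66, 0.90), 0.05, 0.54, 1.36),
        "mean": (0.92, 0.74, 0.84, (0.73, 0.95), 126.93, 0.66, 1.90),
        "sd": (0.83, 0.48, 0.66, (0.53, 0.80), 28.22, 0.31, 0.84),
        "median": (0.92, 0.74, 0.85, (0.74, 0.95), 124.50, 0.66, 1.90),
        "mode": (0.83, 0.70, 0.82, (0.71, 0.93), 133.50, 0.54, 1.36),
        "kurtosis": (0.89, 0.63, 0.74, (0.60, 0.87), 0.015, 0.52, 1.44),
        "skewness": (0.83, 0.67, 0.74, (0.60, 0.87), 0.14, 0.50, 1.27),
    }
)

GRADE_2_VS_3 = _rows(
    {
        "total_area": (0.78, 0.81, 0.80, (0.65, 0.95), 123.97, 0.59, 1.50),
        "minimum": (0.71, 0.69, 0.74, (0.57, 0.91), 79.50, 0.40, 0.94),
        "energy": (0.71, 0.84, 0.78, (0.62, 0.93), 248.19, 0.55, 1.41),
        "relative_energy": (0.74, 0.88, 0.81, (0.67, 0.96), 0.72, 0.62, 1.65),
        "sd_irregularity": (0.89, 0.69, 0.82, (0.68, 0.97), 0.12, 0.58, 1.58),
        "mean": (0.78, 0.88, 0.83, (0.68, 0.97), 150.69, 0.65, 1.76),
        "sd": (0.82, 0.69, 0.80, (0.65, 0.95), 32.36, 0.50, 1.25),
        "median": (0.70, 0.88, 0.83, (0.69, 0.97), 160.50, 0.58, 1.55),
        "mode": (0.96, 0.63, 0.80, (0.63, 0.96), 183.00, 0.59, 2.08),
        "kurtosis": (0.82, 0.75, 0.82, (0.68, 0.96), 0.013, 0.57, 1.42),
        "skewness": (0.93, 0.69, 0.84, (0.70, 0.97), 0.12, 0.61, 1.83),
    }
)

#: Published agreement (accuracy, kappa, F-measure) between the objective
#: cut-off grading and the subjective interference-pattern scale.
AGREEMENT = MappingProxyType(
    {
        "total_area": (0.72, 0.73, 0.84),
        "minimum": (0.68, 0.66, 0.81),
        "energy": (0.72, 0.73, 0.84),
        "relative_energy": (0.76, 0.76, 0.86),
        "sd_irregularity": (0.71, 0.73, 0.83),
        "mean": (0.77, 0.77, 0.87),
        "sd": (0.63, 0.61, 0.78),
        "median": (0.76, 0.77, 0.86),
        "mode": (0.71, 0.67, 0.83),
        "kurtosis": (0.69, 0.69, 0.82),
        "skewness": (0.70, 0.69, 0.82),
    }
)

#: Subjects scoring *above* the cut-off in kurtosis or skewness fall in the
#: thinner-LLT group; for every other metric higher values mean thicker.
DIRECTIONS = MappingProxyType(
    {
        name: ("higher_is_thinner" if name in ("kurtosis", "skewness") else "higher_is_thicker")
        for name in SCREENING
    }
)
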