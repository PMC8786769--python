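"""Model/Results interface for calibrating and validating the grading method.

``LipidLayerGradingModel`` holds a tidy cohort table (one row per subject or
per subject x replicate, with one column per reflectivity metric and a
subjective LLT grade column).  ``fit`` calibrates Youden-optimal cut-offs
per metric via ROC analysis and returns a ``LipidLayerGradingResults``
carrying the cut-off table, per-boundary ROC statistics with bootstrap AUC
intervals, agreement of the objective grading with the subjective labels,
and (when replicates are present) within-subject repeatability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InputError
from .grading import BOUNDARIES, CutoffTable, calibrate_cutoffs, classify_grade
from .metrics import METRIC_NAMES
from .validation_stats import (
    AgreementResult,
    RepeatabilityResult,
    ROCResult,
    agreement,
    repeatability,
)

__all__ = ["LipidLayerGradingModel", "LipidLayerGradingResults"]


class LipidLayerGradingModel:
    """Single-metric LLT grading calibrated on a cohort.

    Parameters
    ----------
    data : DataFrame
        Tidy cohort table.  Required: the metric columns and ``grade_col``
        (subjective grades 1-4; 3 and 4 are merged to 3+ internally).
        Optional: ``subject_col`` and ``replicate_col``; when present,
        calibration runs on per-subject replicate means and repeatability on
        the replicates.
    metrics : sequence of str, optional
        Metric columns to calibrate; defaults to the canonical twelve
        restricted to columns present in ``data``.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        metrics=None,
        *,
        grade_col: str = "grade",
        subject_col: str = "subject",
        replicate_col: str = "replicate",
    ):
        if grade_col not in data.columns:
            raise InputError(f"data has no grade column {grade_col!r}")
        if metrics is None:
            metrics = [m for m in METRIC_NAMES if m in data.columns]
        missing = [m for m in metrics if m not in data.columns]
        if missing:
            raise InputError(f"metric columns missing from data: {missing}")
        if not metrics:
            raise InputError("no metric columns found")
        self.data = data.reset_index(drop=True)
        self.metrics = tuple(metrics)
        self.grade_col = grade_col
        self.subject_col = subject_col if subject_col in data.columns else None
        self.replicate_col = replicate_col if replicate_col in data.columns else None

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kw) -> "LipidLayerGradingModel":
        return cls(data, **kw)

    def _subject_level(self) -> pd.DataFrame:
        """Collapse replicates to per-subject means for calibration."""
        if self.subject_col is None:
            return self.data
        agg = {m: "mean" for m in self.metrics}
        agg[self.grade_col] = "first"
        return self.data.groupby(self.subject_col, as_index=False).agg(agg)

    def fit(self, *, n_boot: int = 2000, seed: int = 0, strict: bool = True) -> "LipidLayerGradingResults":
        """Calibrate cut-offs and evaluate the grading on the cohort."""
        subject_df = self._subject_level()
        grades = np.minimum(subject_df[self.grade_col].to_numpy(dtype=int), 3)
        cutoffs, rocs = calibrate_cutoffs(
            subject_df[list(self.metrics)],
            subject_df[self.grade_col].to_numpy(dtype=int),
            metrics=self.metrics,
            n_boot=n_boot,
            seed=seed,
            strict=strict,
        )
        predicted = pd.DataFrame(index=subject_df.index)
        agreements: dict[str, AgreementResult] = {}
        for m in cutoffs.metrics:
            predicted[m] = [classify_grade(v, m, cutoffs) for v in subject_df[m]]
            ok = predicted[m].notna()
            agreements[m] = agreement(
                predicted.loc[ok, m].astype(int), grades[ok.to_numpy()], n_grades=3
            )
        if self.subject_col is not None:
            predicted.insert(0, self.subject_col, subject_df[self.subject_col])

        repeat: dict[str, RepeatabilityResult] = {}
        has_replicates = (
            self.subject_col is not None
            and self.replicate_col is not None
            and self.data.groupby(self.subject_col).size().max() >= 2
        )
        if has_replicates:
            for m in cutoffs.metrics:
                repeat[m] = repeatability(
                    self.data[m], subjects=self.data[self.subject_col]
                )
        return LipidLayerGradingResults(
            model=self,
            cutoffs=cutoffs,
            roc=rocs,
            agreement=agreements,
            repeatability=repeat,
            predicted=predicted,
            subject_data=subject_df,
        )


@dataclass
class LipidLayerGradingResults:
    """Fitted cut-offs, their diagnostics and cohort-level validation."""

    model: LipidLayerGradingModel
    cutoffs: CutoffTable
    roc: dict[str, dict[str, ROCResult]]
    agreement: dict[str, AgreementResult]
    repeatability: dict[str, RepeatabilityResult]
    predicted: pd.DataFrame
    subject_data: pd.DataFrame

    def predict(self, values: pd.DataFrame) -> pd.DataFrame:
        """Grade new per-subject metric values with the fitted cut-offs."""
        out = pd.DataFrame(index=values.index)
        for m in self.cutoffs.metrics:
            if m in values.columns:
                out[m] = [classify_grade(v, m, self.cutoffs) for v in values[m]]
        return out

    def diagnostics_frame(self) -> pd.DataFrame:
        """Per-metric, per-boundary ROC table (long layout)."""
        rows = []
        for m, per_boundary in self.roc.items():
            for boundary in BOUNDARIES:
                r = per_boundary[boundary]
                rows.append(
                    {
                        "metric": m,
                        "boundary": boundary,
                        "auc": r.auc,
                        "auc_lo": r.auc_ci[0],
                        "auc_hi": r.auc_ci[1],
                        "cutoff": r.cutoff,
                        "sensitivity": r.sensitivity,
                        "specificity": r.specificity,
                        "youden_j": r.youden_j,
                        "discriminant_power": r.discriminant_power,
                        "direction": r.direction,
                    }
                )
        return pd.DataFrame(rows)

    def agreement_frame(self) -> pd.DataFrame:
        rows = []
        for m, a in self.agreement.items():
            row = {
                "metric": m,
                "accuracy": a.accuracy,
                "kappa": a.kappa,
                "weighted_kappa": a.weighted_kappa,
                "f_measure": a.f_measure,
                "f_measure_macro": a.f_measure_macro,
            }
            if m in self.repeatability:
                r = self.repeatability[m]
                row.update(sw=r.sw, cor=r.cor, cov=r.cov)
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable calibration and validation report."""
        lines = ["Lipid layer thickness grading -- calibration summary", "=" * 72]
        n = len(self.subject_data)
        lines.append(f"subjects: {n}    metrics: {len(self.cutoffs.metrics)}")
        lines.append("")
        diag = self.diagnostics_frame()
        screen = diag[diag.boundary == "screening"].set_index("metric")
        tab = pd.DataFrame(
            {
                "direction": [self.cutoffs[m].direction.value for m in self.cutoffs.metrics],
                "cut 1|2": [self.cutoffs[m].grade_1_2 for m in self.cutoffs.metrics],
                "cut 2|3": [self.cutoffs[m].grade_2_3 for m in self.cutoffs.metrics],
                "AUC(1 vs rest)": screen.loc[list(self.cutoffs.metrics), "auc"],
                "Se": screen.loc[list(self.cutoffs.metrics), "sensitivity"],
                "Sp": screen.loc[list(self.cutoffs.metrics), "specificity"],
                "J": screen.loc[list(self.cutoffs.metrics), "youden_j"],
            },
            index=list(self.cutoffs.metrics),
        )
        lines.append(tab.round(3).to_string())
        lines.append("")
        lines.append("Agreement with the subjective grading (3 and 4 merged to 3+):")
        lines.append(self.agreement_frame().round(3).to_string(index=False))
        return "\n".join(lines)

    def plot_roc(self, metric: str, boundary: str = "screening", ax=None):
        """Empirical ROC curve of one metric for one grade boundary."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.subject_data
        merged = np.minimum(df[self.model.grade_col].to_numpy(dtype=int), 3)
        subsets = {
            "screening": (np.ones_like(merged, dtype=bool), merged == 1),
            "grade_1_2": (np.isin(merged, (1, 2)), merged == 1),
            "grade_2_3": (np.isin(merged, (2, 3)), merged == 2),
        }
        subset, positive = subsets[boundary]
        v = df[metric].to_numpy(dtype=float)[subset]
        y = positive[subset]
        r = self.roc[metric][boundary]
        sign = 1.0 if r.direction == "higher" else -1.0
        thresholds = np.unique(sign * v)
        pts = [
            (np.mean(sign * v[~y] > t), np.mean(sign * v[y] > t)) for t in thresholds
        ]
        pts = [(1.0, 1.0)] + pts + [(0.0, 0.0)]
        fpr, tpr = zip(*sorted(pts))
        ax.plot(fpr, tpr, drawstyle="steps-post", label=f"{metric} (AUC {r.auc:.2f})")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"{metric}: {boundary}")
        ax.legend()
        return ax
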