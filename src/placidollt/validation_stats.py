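"""Repeatability, ROC / diagnostic-ability and agreement statistics.

These routines operate on tidy tables of metric values, decoupled from the
imaging chain, so they apply to any per-subject metric.

Repeatability follows the Bland-Altman convention: the within-subject SD Sw
is the square root of the mean within-subject sample variance, the
repeatability coefficient is CoR = 2.77 * Sw (1.96 * sqrt(2)), and CoV
expresses Sw as a percentage of the grand mean.

ROC analysis uses the Mann-Whitney concordance estimator for the AUC (tied
pairs credited 0.5), candidate thresholds at midpoints between consecutive
sorted unique values, the Youden-optimal cut-off (ties broken toward higher
specificity -- fewer false alarms in a screening context) and a stratified
bootstrap for the AUC confidence interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score, confusion_matrix, f1_score

from .exceptions import EmptyInputError, InputError, ParameterError

__all__ = [
    "COR_CONSTANT",
    "RepeatabilityResult",
    "ROCResult",
    "AgreementResult",
    "repeatability",
    "roc_analysis",
    "youden_index",
    "discriminant_power",
    "agreement",
]

#: Bland-Altman repeatability constant, 1.96 * sqrt(2).
COR_CONSTANT = 2.77


@dataclass(frozen=True)
class RepeatabilityResult:
    """Within-subject repeatability of one metric."""

    sw: float
    cor: float
    cov: float
    n_subjects: int
    n_excluded: int = 0


def repeatability(values, subjects=None) -> RepeatabilityResult:
    """Within-subject SD, repeatability coefficient and CoV.

    ``values``/``subjects`` may be parallel 1-D arrays (long format), or
    ``values`` alone a 2-D array / wide DataFrame of one row per subject and
    one column per replicate.  Subjects with fewer than 2 non-missing
    replicates are excluded with a warning.
    """
    if subjects is None:
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 2:
            raise InputError("without subject ids, values must be a 2-D replicate table")
        groups = [row[~np.isnan(row)] for row in arr]
    else:
        df = pd.DataFrame({"subject": np.asarray(subjects), "value": np.asarray(values, dtype=float)})
        df = df.dropna(subset=["value"])
        groups = [g.to_numpy() for _, g in df.groupby("subject")["value"]]

    kept = [g for g in groups if g.size >= 2]
    n_excluded = len(groups) - len(kept)
    if n_excluded:
        warnings.warn(
            f"excluded {n_excluded} subject(s) with fewer than 2 replicates", stacklevel=2
        )
    if not kept:
        raise EmptyInputError("no subject has at least 2 replicates")

    within_var = np.array([g.var(ddof=1) for g in kept])
    sw = float(np.sqrt(within_var.mean()))
    grand_mean = float(np.concatenate(kept).mean())
    cov = math.nan if grand_mean == 0 else 100.0 * sw / abs(grand_mean)
    return RepeatabilityResult(
        sw=sw, cor=COR_CONSTANT * sw, cov=cov, n_subjects=len(kept), n_excluded=n_excluded
    )


@dataclass(frozen=True)
class ROCResult:
    """Diagnostic ability of one metric for one binary contrast."""

    auc: float
    auc_ci: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    discriminant_power: float
    direction: str  # 'higher' or 'lower': side of the positive class
    n_positive: int = 0
    n_negative: int = 0

    @property
    def is_discriminative(self) -> bool:
        """False when the bootstrap AUC interval still covers chance (0.5)."""
        return self.auc_ci[0] > 0.5


def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney AUC with 0.5 credit for ties, via midranks."""
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    n_pos, n_neg = pos.size, neg.size
    return float((ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_analysis(
    values,
    labels,
    *,
    positive=1,
    direction: str | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> ROCResult:
    """ROC analysis of a continuous metric against a binary label.

    The direction is auto-detected (the positive class sits on the side of
    its higher mean); the score is flipped internally so AUC measures
    concordance with the positive class.  The reported cut-off lives in the
    original value space: with direction 'higher' a case is called positive
    when its value exceeds the cut-off, with 'lower' when it falls below.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise InputError("values and labels must have equal length")
    pos = values[labels == positive]
    neg = values[labels != positive]
    if pos.size == 0 or neg.size == 0:
        raise InputError("both classes must be non-empty")

    if direction is None:
        direction = "higher" if pos.mean() >= neg.mean() else "lower"
    elif direction not in ("higher", "lower"):
        raise ParameterError(f"direction must be 'higher' or 'lower', got {direction!r}")
    sign = 1.0 if direction == "higher" else -1.0

    auc = _rank_auc(sign * pos, sign * neg)

    uniq = np.unique(values)
    if uniq.size >= 2:
        thresholds = (uniq[:-1] + uniq[1:]) / 2.0
    else:
        thresholds = uniq  # degenerate: single observed value
    best = None
    for thr in thresholds:
        if direction == "higher":
            se = float(np.mean(pos > thr))
            sp = float(np.mean(neg <= thr))
        else:
            se = float(np.mean(pos < thr))
            sp = float(np.mean(neg >= thr))
        j = se + sp - 1.0
        # maximise J; ties broken toward higher specificity, then lower thr
        key = (round(j, 12), round(sp, 12))
        if best is None or key > best[0]:
            best = (key, thr, se, sp, j)
    _, cutoff, se, sp, j = best

    rng = np.random.default_rng(seed)
    if n_boot > 0:
        boots = np.empty(n_boot)
        for b in range(n_boot):
            bp = rng.choice(pos, size=pos.size, replace=True)
            bn = rng.choice(neg, size=neg.size, replace=True)
            boots[b] = _rank_auc(sign * bp, sign * bn)
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    else:
        ci = (math.nan, math.nan)

    return ROCResult(
        auc=auc,
        auc_ci=ci,
        cutoff=float(cutoff),
        sensitivity=se,
        specificity=sp,
        youden_j=j,
        discriminant_power=discriminant_power(se, sp),
        direction=direction,
        n_positive=int(pos.size),
        n_negative=int(neg.size),
    )


def youden_index(sensitivity: float, specificity: float) -> float:
    """J = sensitivity + specificity - 1."""
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ParameterError("sensitivity and specificity must lie in [0, 1]")
    return sensitivity + specificity - 1.0


def discriminant_power(sensitivity: float, specificity: float) -> float:
    """DP = (sqrt(3)/pi) * (logit(Se) + logit(Sp)).

    Summarises how well a test separates the groups; unbounded (returned as
    +/-inf, not an exception) when Se or Sp hits 0 or 1.
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ParameterError("sensitivity and specificity must lie in [0, 1]")

    def logit(p: float) -> float:
        if p == 0:
            return -math.inf
        if p == 1:
            return math.inf
        return math.log(p / (1 - p))

    s = logit(sensitivity) + logit(specificity)
    if math.isnan(s):
        return math.nan
    return (math.sqrt(3.0) / math.pi) * s if math.isfinite(s) else s


@dataclass(frozen=True)
class AgreementResult:
    """Agreement between objective and subjective ordinal grades."""

    accuracy: float
    kappa: float
    weighted_kappa: float
    f_measure: float
    f_measure_macro: float
    confusion: np.ndarray
    labels: tuple[int, ...]


def agreement(predicted, subjective, n_grades: int | None = None) -> AgreementResult:
    """Accuracy, Cohen's kappa, quadratic-weighted kappa and F-measure.

    Grades are integers 1..G.  The quadratic weights are
    w_ij = 1 - (i - j)^2 / (G - 1)^2.  The headline F-measure is the F1 of
    the binary altered-vs-normal collapse with *normal* (grade >= 2) as the
    positive class; the macro-averaged F1 over all grades is also reported
    since the positive-class convention is not universal.
    """
    pred = np.asarray(predicted, dtype=int)
    subj = np.asarray(subjective, dtype=int)
    if pred.shape != subj.shape:
        raise InputError("grade vectors must have equal length")
    g = int(n_grades) if n_grades is not None else int(max(pred.max(), subj.max()))
    if pred.min() < 1 or subj.min() < 1 or pred.max() > g or subj.max() > g:
        raise InputError(f"grades must lie in 1..{g}")
    labels = list(range(1, g + 1))

    cm = confusion_matrix(subj, pred, labels=labels)
    accuracy = float(np.trace(cm) / cm.sum())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        kappa = float(cohen_kappa_score(subj, pred, labels=labels))
        wkappa = (
            float(cohen_kappa_score(subj, pred, labels=labels, weights="quadratic"))
            if g > 1
            else kappa
        )
        f_macro = float(f1_score(subj, pred, labels=labels, average="macro", zero_division=0))
        f_bin = float(
            f1_score((subj >= 2).astype(int), (pred >= 2).astype(int), pos_label=1, zero_division=0)
        )
    return AgreementResult(
        accuracy=accuracy,
        kappa=kappa,
        weighted_kappa=wkappa,
        f_measure=f_bin,
        f_measure_macro=f_macro,
        confusion=cm,
        labels=tuple(labels),
    )
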