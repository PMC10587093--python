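"""ROC analysis, partial AUC, bootstrap and Wilson confidence intervals, and
specificity-anchored threshold selection.

Conventions used throughout the package:

- A positive call is made when score >= cutoff; equal scores form a single
  operating point (standard staircase ROC).
- AUC is the concordance probability P(score_case > score_control) with ties
  counting 1/2, identical to the trapezoidal area under the staircase.
- Partial AUC is the *unnormalized* trapezoidal area of the ROC over
  FPR in [0, 1 - spec_min] with linear interpolation at the band edge, so a
  perfect classifier scores 1 - spec_min (0.10 at the default 90% band) and
  chance scores (1 - spec_min)^2 / 2.
- Binomial CIs are two-sided Wilson score intervals with the exact normal
  quantile; AUC CIs are percentile bootstrap, stratified by class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)

__all__ = [
    "RocCurve",
    "BinomialCI",
    "AucCI",
    "roc_curve",
    "partial_auc",
    "wilson_interval",
    "bootstrap_auc_ci",
    "threshold_for_specificity",
    "confusion_summary",
    "ConfusionSummary",
]


@dataclass
class RocCurve:
    """Operating points (threshold, sensitivity, specificity) and AUC.

    Points are sorted by ascending threshold: sensitivity is non-increasing
    and specificity non-decreasing along the curve, with both trivial
    endpoints (sens=1/spec=0 and sens=0/spec=1) included.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_cases: int
    n_controls: int

    @property
    def fpr(self) -> np.ndarray:
        return 1.0 - self.specificity

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "sensitivity": self.sensitivity, "specificity": self.specificity}
        )


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC curve and AUC (concordance probability, ties count 1/2)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    n_cases = int((labels == 1).sum())
    n_controls = int((labels == 0).sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError("ROC requires at least one case and one control")
    fpr, tpr, thr = skm.roc_curve(labels, scores)
    auc = float(skm.roc_auc_score(labels, scores))
    # sklearn orders by descending threshold (first is +inf); flip ascending
    order = slice(None, None, -1)
    return RocCurve(
        thresholds=thr[order].copy(),
        sensitivity=tpr[order].copy(),
        specificity=1.0 - fpr[order],
        auc=auc,
        n_cases=n_cases,
        n_controls=n_controls,
    )


def partial_auc(roc: RocCurve, spec_min: float = 0.90) -> float:
    """Unnormalized ROC area over FPR in [0, 1 - spec_min]."""
    if not 0 <= spec_min < 1:
        raise ValueError("spec_min must be in [0, 1)")
    fpr_max = 1.0 - spec_min
    fpr = roc.fpr[::-1]  # ascending FPR
    tpr = roc.sensitivity[::-1]
    tpr_edge = float(np.interp(fpr_max, fpr, tpr))
    keep = fpr < fpr_max
    xs = np.append(fpr[keep], fpr_max)
    ys = np.append(tpr[keep], tpr_edge)
    return float(np.trapezoid(ys, xs))


@dataclass(frozen=True)
class BinomialCI:
    successes: int
    trials: int
    level: float
    lower: float
    upper: float

    @property
    def proportion(self) -> float:
        return self.successes / self.trials

    def as_percent(self, decimals: int = 1) -> tuple[float, float, float]:
        """(point, lower, upper) in %, rounded for tabulation."""
        return (
            round(100 * self.proportion, decimals),
            round(100 * self.lower, decimals),
            round(100 * self.upper, decimals),
        )


def wilson_interval(successes: int, trials: int, level: float = 0.95) -> BinomialCI:
    """Two-sided Wilson score interval for a binomial proportion."""
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes must be in [0, trials]")
    lower, upper = proportion_confint(successes, trials, alpha=1 - level, method="wilson")
    # boundary cases are exact analytically; clean up float residue
    if successes == 0:
        lower = 0.0
    if successes == trials:
        upper = 1.0
    return BinomialCI(successes, trials, level, float(lower), float(upper))


@dataclass(frozen=True)
class AucCI:
    auc: float
    lower: float
    upper: float
    n_reps: int
    seed: int


def bootstrap_auc_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    n_reps: int = 2000,
    level: float = 0.95,
    seed: int = 0,
    stratified: bool = True,
) -> AucCI:
    """Percentile bootstrap CI of the AUC.

    By default cases and controls are resampled separately with their sizes
    preserved, so every resample contains both classes.  In non-stratified
    mode a degenerate single-class resample is redrawn (and logged).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    point = roc_curve(scores, labels).auc
    aucs = np.empty(n_reps)
    if stratified:
        for k in range(n_reps):
            c = rng.choice(cases, size=cases.size, replace=True)
            u = rng.choice(controls, size=controls.size, replace=True)
            aucs[k] = roc_curve(np.concatenate([c, u]), np.r_[np.ones(c.size), np.zeros(u.size)]).auc
    else:
        n = scores.size
        k = 0
        while k < n_reps:
            idx = rng.integers(0, n, size=n)
            if labels[idx].min() == labels[idx].max():
                logger.info("bootstrap resample lost a class; redrawn")
                continue
            aucs[k] = roc_curve(scores[idx], labels[idx]).auc
            k += 1
    alpha = 1 - level
    lower, upper = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return AucCI(auc=point, lower=float(lower), upper=float(upper), n_reps=n_reps, seed=seed)


def threshold_for_specificity(control_scores: np.ndarray, target_spec: float = 0.91) -> float:
    """Smallest cutoff whose training specificity reaches the target.

    Specificity of cutoff c is the fraction of control scores strictly below
    c (calls are score >= c).  Returns the smallest observed control score
    achieving specificity >= target, or a value just above the maximum when
    no observed score suffices (target 1.0).
    """
    if not 0 < target_spec <= 1:
        raise ValueError("target_spec must be in (0, 1]")
    control_scores = np.asarray(control_scores, float)
    if control_scores.size == 0:
        raise ValueError("control scores must be non-empty")
    n = control_scores.size
    for c in np.unique(control_scores):
        if (control_scores < c).sum() / n >= target_spec:
            return float(c)
    return float(np.nextafter(control_scores.max(), np.inf))


@dataclass
class ConfusionSummary:
    """Sensitivity (overall and per stage) and specificity with Wilson CIs."""

    sensitivity: BinomialCI | None
    specificity: BinomialCI | None
    stage_sensitivity: dict[str, BinomialCI] = field(default_factory=dict)

    def to_frame(self, decimals: int = 1) -> pd.DataFrame:
        rows = []

        def add(name: str, ci: BinomialCI | None):
            if ci is None:
                return
            pt, lo, hi = ci.as_percent(decimals)
            rows.append({"metric": name, "n": ci.trials, "successes": ci.successes,
                         "percent": pt, "ci_lower": lo, "ci_upper": hi})

        add("sensitivity", self.sensitivity)
        for stage, ci in self.stage_sensitivity.items():
            add(f"stage_{stage}_sensitivity", ci)
        add("specificity", self.specificity)
        return pd.DataFrame(rows)


def confusion_summary(
    calls: np.ndarray,
    labels: np.ndarray,
    stages: np.ndarray | None = None,
    level: float = 0.95,
) -> ConfusionSummary:
    """Table-style performance summary of binary calls against labels."""
    calls = np.asarray(calls).astype(bool)
    labels = np.asarray(labels).astype(int)
    if calls.shape != labels.shape:
        raise ValueError("calls not aligned with labels")
    cases, controls = labels == 1, labels == 0

    def ci_or_none(successes: int, trials: int, what: str):
        if trials == 0:
            warnings.warn(f"no patients in stratum {what!r}; CI omitted")
            return None
        return wilson_interval(successes, trials, level)

    out = ConfusionSummary(
        sensitivity=ci_or_none(int(calls[cases].sum()), int(cases.sum()), "cases"),
        specificity=ci_or_none(int((~calls[controls]).sum()), int(controls.sum()), "controls"),
    )
    if stages is not None:
        stages = np.asarray(stages)
        for stage in ("I", "II"):
            sel = cases & (stages == stage)
            ci = ci_or_none(int(calls[sel].sum()), int(sel.sum()), f"stage {stage}")
            if ci is not None:
                out.stage_sensitivity[stage] = ci
    return out
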