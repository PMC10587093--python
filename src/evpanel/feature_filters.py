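"""Filter-based feature selection for censored biomarker panels.

Two filters are applied before any model fitting:

1. Reliability: drop biomarkers whose LLoD-imputation fraction exceeds a
   cutoff (default <=50% of patients imputed; the stricter locked-model
   setting uses <=30%).  The cutoff is inclusive.
2. Redundancy: among remaining biomarkers, any pair whose absolute Pearson
   correlation exceeds a cutoff (default 0.9; locked-model 0.5) is resolved
   by a two-sample Kolmogorov-Smirnov test of each member against the binary
   case/control response — the member with the *higher* KS p-value (weaker
   case/control separation) is dropped.  Cliques are resolved greedily in
   descending |r|; ties in p fall to the later biomarker in schema order, so
   the result is deterministic.

Pearson r and KS statistics are computed on raw post-imputation
concentrations (imputed cells participate at their LLoD value).  KS p-values
use the two-sided asymptotic Kolmogorov distribution and are used only
ordinally, so no multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel_data import CohortDataset, imputation_fraction

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "KsResult",
    "FilterReport",
    "imputation_rate_filter",
    "ks_two_sample",
    "correlation_ks_filter",
]


@dataclass(frozen=True)
class FilterConfig:
    max_imputed_fraction: float = 0.5
    max_abs_correlation: float = 0.9

    def __post_init__(self):
        if not 0 <= self.max_imputed_fraction <= 1:
            raise ValueError("max_imputed_fraction must be in [0, 1]")
        if not 0 <= self.max_abs_correlation <= 1:
            raise ValueError("max_abs_correlation must be in [0, 1]")


#: locked-model filter settings (stricter imputation and correlation cutoffs)
LOCKED_MODEL_FILTERS = FilterConfig(max_imputed_fraction=0.3, max_abs_correlation=0.5)


@dataclass(frozen=True)
class KsResult:
    statistic: float
    p_value: float


@dataclass
class Removal:
    biomarker: str
    partner: str
    r: float
    ks_p_removed: float
    ks_p_partner: float
    reason: str


@dataclass
class FilterReport:
    """Per-biomarker audit trail of both filters."""

    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=["biomarker", "imputed_fraction", "kept", "reason", "partner", "r", "ks_p"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def imputation_rate_filter(
    dataset: CohortDataset,
    config: FilterConfig = FilterConfig(),
    report: FilterReport | None = None,
) -> list[str]:
    """Biomarkers reliably measured: imputation fraction <= cutoff (inclusive)."""
    if dataset.n_patients == 0:
        raise ValueError("empty dataset")
    kept = []
    for b in dataset.schema.biomarkers:
        frac = imputation_fraction(dataset, b)
        ok = frac <= config.max_imputed_fraction
        if ok:
            kept.append(b)
        if report is not None:
            report.rows.append(
                {"biomarker": b, "imputed_fraction": frac, "kept": ok,
                 "reason": "" if ok else f"imputed fraction {frac:.3f} > {config.max_imputed_fraction}",
                 "partner": "", "r": np.nan, "ks_p": np.nan}
            )
    return kept


def ks_two_sample(x: np.ndarray, y: np.ndarray) -> KsResult:
    """Two-sample KS: D = sup |ECDF_x - ECDF_y|, asymptotic two-sided p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("KS test requires non-empty samples")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return KsResult(statistic=float(res.statistic), p_value=float(res.pvalue))


def correlation_ks_filter(
    dataset: CohortDataset,
    candidates: list[str],
    labels: np.ndarray,
    config: FilterConfig = FilterConfig(),
    report: FilterReport | None = None,
) -> tuple[list[str], list[Removal]]:
    """Drop the weaker member (higher KS p vs the response) of each
    over-correlated pair; greedy over pairs in descending |r|.

    Returns (kept names in schema order, removals with both p-values).
    Constant-valued biomarkers have undefined Pearson r; they are flagged,
    treated as uncorrelated with everything, and always survive this filter.
    """
    if len(candidates) < 2:
        return list(candidates), []
    labels = np.asarray(labels)
    if labels.shape[0] != dataset.n_patients:
        raise ValueError("labels not aligned with dataset patients")
    X = np.column_stack([dataset.column(b) for b in candidates])
    sd = X.std(axis=0)
    constant = sd == 0
    for b, c in zip(candidates, constant):
        if c:
            logger.warning("biomarker %s is constant; Pearson r undefined, treated as uncorrelated", b)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr[np.ix_(constant, np.arange(len(candidates)))] = 0.0
    corr[np.ix_(np.arange(len(candidates)), np.nonzero(constant)[0])] = 0.0
    np.fill_diagonal(corr, 1.0)

    ks_p = {}

    def pval(i: int) -> float:
        if i not in ks_p:
            ks_p[i] = ks_two_sample(X[labels == 1, i], X[labels == 0, i]).p_value
        return ks_p[i]

    alive = set(range(len(candidates)))
    pairs = [
        (abs(corr[i, j]), i, j)
        for i in range(len(candidates))
        for j in range(i + 1, len(candidates))
        if abs(corr[i, j]) > config.max_abs_correlation
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    removals: list[Removal] = []
    for r_abs, i, j in pairs:
        if i not in alive or j not in alive:
            continue
        pi, pj = pval(i), pval(j)
        # drop the higher p (weaker separation); tie -> later in schema order
        if pi > pj:
            drop, keep = i, j
        else:
            drop, keep = j, i
        alive.discard(drop)
        removals.append(
            Removal(
                biomarker=candidates[drop],
                partner=candidates[keep],
                r=float(corr[i, j]),
                ks_p_removed=pval(drop),
                ks_p_partner=pval(keep),
                reason=f"|r|={r_abs:.3f} > {config.max_abs_correlation} with {candidates[keep]}; higher KS p",
            )
        )
    kept = [candidates[i] for i in sorted(alive)]
    if report is not None:
        removed_names = {rm.biomarker: rm for rm in removals}
        for idx, b in enumerate(candidates):
            rm = removed_names.get(b)
            report.rows.append(
                {"biomarker": b, "imputed_fraction": np.nan, "kept": rm is None,
                 "reason": rm.reason if rm else "", "partner": rm.partner if rm else "",
                 "r": rm.r if rm else np.nan, "ks_p": rm.ks_p_removed if rm else pval(idx) if idx in ks_p else np.nan}
            )
    return kept, removals
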