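"""Synthetic case/control cohorts with the statistical structure of a
multiplex EV-protein panel study.

The generator emulates, at user-configurable scale, the features the
classifier-development pipeline has to cope with: a few hundred patients
split into stage I/II cases and controls, ~50 positive right-skewed biomarker
concentrations (log-normal), a small informative subset shifted in cases on
the log2 scale, blocks of highly correlated markers, left-censoring at
biomarker-specific LLoDs, and replicate measurements per patient for
within-patient CV estimation.

Concentrations are built on the log2 scale: marker i of patient j is

    log2 x_ij = mu_i + L z_j + delta_i y_j

with z a standard normal latent vector, L a Cholesky-like mixing matrix that
induces the configured correlation blocks, delta_i the case shift (log2
units) of informative markers and y_j the case indicator.  Censoring places
each marker's LLoD at the configured quantile of its control distribution and
then applies the same LLoD imputation rule used for real data, so the mask
semantics are identical.

A single seed drives a hierarchical RNG (cohort stream, replicate stream),
so cohorts and replicates can be regenerated independently and reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel_data import CohortDataset, PanelSchema, PatientRecord, impute_llod
from .robustness import ReplicateMeasurements

__all__ = ["SyntheticConfig", "default_study_config", "generate_cohort", "generate_replicates"]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    informative_set maps biomarker index -> case shift in log2 units.
    correlated_blocks is a list of (indices, target Pearson r) pairs; within a
    block every pair shares the target r (equicorrelation via a common latent
    factor).  censor_fraction maps biomarker index -> target fraction of
    controls below the LLoD.  within_patient_cv maps biomarker index -> true
    CV (sd/mean) of replicate measurements.
    """

    n_cases_stage1: int = 39
    n_cases_stage2: int = 66
    n_controls: int = 545
    n_biomarkers: int = 52
    informative_set: dict[int, float] = field(default_factory=dict)
    correlated_blocks: list[tuple[list[int], float]] = field(default_factory=list)
    censor_fraction: dict[int, float] = field(default_factory=dict)
    within_patient_cv: dict[int, float] = field(default_factory=dict)
    n_replicates: int = 3
    log2_sd: float = 1.0
    log2_mean_low: float = 3.0
    log2_mean_high: float = 9.0
    seed: int = 0
    #: seed of the population structure (baseline marker means); kept separate
    #: from the sampling seed so cohorts drawn with different seeds are
    #: matched draws from the same population, as a training/validation pair
    #: from one study would be
    population_seed: int = 2026

    def __post_init__(self):
        for name in ("n_cases_stage1", "n_cases_stage2", "n_controls", "n_biomarkers"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for idx, r in self.correlated_blocks:
            if not -1 < r < 1:
                raise ValueError(f"correlation target must be in (-1, 1), got {r}")
            if len(idx) > 2 and r < 0:
                raise ValueError("negative equicorrelation is infeasible for blocks of size > 2")
        if any(not 0 <= f <= 1 for f in self.censor_fraction.values()):
            raise ValueError("censor fractions must be in [0, 1]")
        if any(cv < 0 for cv in self.within_patient_cv.values()):
            raise ValueError("within-patient CVs must be >= 0")

    @property
    def n_patients(self) -> int:
        return self.n_cases_stage1 + self.n_cases_stage2 + self.n_controls


def default_study_config(seed: int = 0) -> SyntheticConfig:
    """The default study-scale configuration.

    650 patients (39 stage I + 66 stage II cases vs 545 controls), 52
    biomarkers of which 7 carry large case shifts (1.2-3.0 log2 units on a
    marker log2-sd of 1), one near-duplicate non-informative pair (r=0.95)
    exercising the correlation filter, one moderate r=0.6
    triple, two heavily censored markers (60% of controls below LLoD)
    exercising the imputation-rate filter, mild 5-20% censoring elsewhere,
    and within-patient CVs of 0.05-0.15 typical of bead-based immunoassays.
    """
    shifts = [3.0, 2.5, 2.0, 2.0, 1.5, 1.5, 1.2]
    informative = {i: s for i, s in enumerate(shifts)}
    blocks = [([40, 41], 0.95), ([10, 11, 12], 0.6)]
    rng = np.random.default_rng(seed + 101)  # fixed structural stream
    censor = {i: 0.6 for i in (20, 21)}
    for i in range(52):
        if i not in censor:
            censor[i] = float(rng.uniform(0.0, 0.2)) if i >= 7 else 0.05
    cvs = {i: float(rng.uniform(0.05, 0.15)) for i in range(52)}
    return SyntheticConfig(
        informative_set=informative,
        correlated_blocks=blocks,
        censor_fraction=censor,
        within_patient_cv=cvs,
        seed=seed,
    )


def _mixing_matrix(config: SyntheticConfig) -> np.ndarray:
    """Per-marker latent loadings inducing the configured correlation blocks.

    Markers outside any block get an independent unit-variance noise column.
    Within a block with target r, each marker loads sqrt(r) on a shared
    factor and sqrt(1-r) on its own noise, giving pairwise correlation r.
    """
    p = config.n_biomarkers
    in_block: dict[int, tuple[int, float]] = {}
    for bi, (idx, r) in enumerate(config.correlated_blocks):
        for i in idx:
            if i in in_block:
                raise ValueError(f"biomarker index {i} appears in multiple correlation blocks")
            if not 0 <= i < p:
                raise ValueError(f"block index {i} out of range")
            in_block[i] = (bi, r)
    n_factors = len(config.correlated_blocks)
    L = np.zeros((p, n_factors + p))
    for i in range(p):
        if i in in_block:
            bi, r = in_block[i]
            sign = 1.0
            if r < 0:  # 2-marker block: anti-correlate via opposite loadings
                idx = config.correlated_blocks[bi][0]
                sign = -1.0 if i == idx[1] else 1.0
                r = -r
            L[i, bi] = sign * np.sqrt(r)
            L[i, n_factors + i] = np.sqrt(1 - r)
        else:
            L[i, n_factors + i] = 1.0
    return L


def generate_cohort(config: SyntheticConfig) -> CohortDataset:
    """Draw one cohort; deterministic given ``config.seed``."""
    ss = np.random.SeedSequence(config.seed)
    cohort_seed, _ = ss.spawn(2)
    rng = np.random.default_rng(cohort_seed)

    n, p = config.n_patients, config.n_biomarkers
    labels = np.array([1] * (config.n_cases_stage1 + config.n_cases_stage2) + [0] * config.n_controls)
    stages = ["I"] * config.n_cases_stage1 + ["II"] * config.n_cases_stage2 + ["none"] * config.n_controls

    mu = np.random.default_rng(config.population_seed).uniform(
        config.log2_mean_low, config.log2_mean_high, size=p
    )
    L = _mixing_matrix(config)
    z = rng.standard_normal((n, L.shape[1]))
    log2x = mu + config.log2_sd * (z @ L.T)
    for i, shift in config.informative_set.items():
        log2x[labels == 1, i] += shift
    x = np.exp2(log2x)

    # LLoD at the configured control quantile; imputation mirrors real data
    controls = labels == 0
    llod = np.empty(p)
    for j in range(p):
        frac = config.censor_fraction.get(j, 0.0)
        if frac > 0 and controls.any():
            llod[j] = float(np.quantile(x[controls, j], frac))
        else:
            llod[j] = max(float(x[:, j].min()) * 0.5, np.finfo(float).tiny)
    schema = PanelSchema([f"BM{j:02d}" for j in range(p)], {f"BM{j:02d}": llod[j] for j in range(p)})
    raw = x.copy()
    raw[raw < llod] = np.nan
    values, mask = impute_llod(raw, schema)

    patients = [
        PatientRecord(f"P{k:04d}", int(labels[k]), stages[k], "none")
        for k in range(n)
    ]
    return CohortDataset(schema, patients, values, mask)


def generate_replicates(cohort: CohortDataset, config: SyntheticConfig) -> ReplicateMeasurements:
    """Replicate measurements with multiplicative within-patient noise.

    Replicates of cell value v are v * exp(sigma Z - sigma^2/2) with
    sigma^2 = ln(1 + CV^2), a mean-preserving log-normal factor whose
    coefficient of variation is exactly the configured CV.  Replicates below
    the biomarker's LLoD are set to the LLoD.
    """
    if config.n_replicates < 2:
        raise ValueError("n_replicates must be >= 2 (CV undefined otherwise)")
    ss = np.random.SeedSequence(config.seed)
    _, rep_seed = ss.spawn(2)
    rng = np.random.default_rng(rep_seed)
    n, p = cohort.values.shape
    cv = np.array([config.within_patient_cv.get(j, 0.0) for j in range(p)])
    sigma = np.sqrt(np.log1p(cv**2))
    z = rng.standard_normal((n, p, config.n_replicates))
    factors = np.exp(sigma[None, :, None] * z - 0.5 * (sigma**2)[None, :, None])
    reps = cohort.values[:, :, None] * factors
    llod = cohort.schema.llod_vector()
    reps = np.maximum(reps, llod[None, :, None])
    return ReplicateMeasurements(
        biomarkers=list(cohort.schema.biomarkers),
        patient_ids=cohort.patient_ids,
        values=reps,
    )
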