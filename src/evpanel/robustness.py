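"""Measurement-noise robustness analysis for a locked classifier.

Three steps: (1) estimate per-biomarker mean within-patient coefficients of
variation (CV = sd/mean of a patient's replicate measurements, averaged over
patients); (2) perturb every concentration multiplicatively under a 68/32
two-band noise rule — with probability 0.68 the value moves by a uniform
relative amount within +/-CV (the "within 1 sd" band), otherwise by a uniform
relative amount between CV and 2CV in a random direction (the "1-2 sd" band);
(3) apply the locked classifier to many perturbed copies and summarize AUC,
specificity and overall/stage-wise sensitivity as mean/min/max.

The noise factor has expectation exactly 1, so perturbation is
mean-preserving.  Labels, stages and the imputation mask are never touched;
a value pushed non-positive (possible only when CV > 0.5 in the outer band)
is clamped to the biomarker's LLoD and counted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_data import CohortDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ReplicateMeasurements",
    "CvProfile",
    "PerturbationSummary",
    "within_patient_cv",
    "perturb_dataset",
    "perturbation_study",
]


@dataclass
class ReplicateMeasurements:
    """Replicate concentrations per (patient, biomarker).

    ``values`` has shape (n_patients, n_biomarkers, n_replicates) with all
    entries > 0 (below-LLoD replicates already set to the LLoD) and
    n_replicates >= 2.
    """

    biomarkers: list[str]
    patient_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (patients, biomarkers, replicates)")
        if self.values.shape[2] < 2:
            raise ValueError("need >= 2 replicates per patient/biomarker")
        if self.values.shape[:2] != (len(self.patient_ids), len(self.biomarkers)):
            raise ValueError("values shape does not match patients x biomarkers")
        if not np.all(self.values > 0):
            raise ValueError("replicate values must be strictly positive")


@dataclass
class CvProfile:
    """Per-biomarker mean (and median) within-patient CV, as fractions."""

    mean_cv: dict[str, float]
    median_cv: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if any(v < 0 for v in self.mean_cv.values()):
            raise ValueError("CVs must be >= 0")

    def vector(self, biomarkers: list[str]) -> np.ndarray:
        missing = [b for b in biomarkers if b not in self.mean_cv]
        if missing:
            raise KeyError(f"CV profile missing biomarkers: {missing}")
        return np.array([self.mean_cv[b] for b in biomarkers])

    @classmethod
    def constant(cls, biomarkers: list[str], cv: float) -> "CvProfile":
        return cls({b: cv for b in biomarkers}, {b: cv for b in biomarkers})


def within_patient_cv(replicates: ReplicateMeasurements) -> CvProfile:
    """Mean within-patient CV per biomarker.

    Per patient/biomarker, CV = sample sd (n-1 denominator) / mean of that
    patient's replicates; the profile value is the unweighted mean (and
    median) across patients.
    """
    sd = replicates.values.std(axis=2, ddof=1)
    mean = replicates.values.mean(axis=2)
    cv = sd / mean  # mean > 0 guaranteed by positivity
    return CvProfile(
        mean_cv={b: float(cv[:, j].mean()) for j, b in enumerate(replicates.biomarkers)},
        median_cv={b: float(np.median(cv[:, j])) for j, b in enumerate(replicates.biomarkers)},
    )


def perturbation_factors(
    shape: tuple[int, int],
    cv: np.ndarray,
    rng: np.random.Generator,
    inner_prob: float = 0.68,
    exact_partition: bool = False,
) -> np.ndarray:
    """Multiplicative 68/32 two-band noise factors, one per cell.

    Inner band (probability ``inner_prob``): factor 1+u, u ~ Uniform(-CV, CV).
    Outer band: factor 1 + s*v with s = +/-1 equiprobable and
    v ~ Uniform(CV, 2 CV).  ``exact_partition`` assigns exactly
    round(inner_prob * n_cells) cells to the inner band instead of
    independent Bernoulli draws.
    """
    n, p = shape
    if exact_partition:
        flat = np.zeros(n * p, dtype=bool)
        flat[: int(round(inner_prob * n * p))] = True
        rng.shuffle(flat)
        inner = flat.reshape(shape)
    else:
        inner = rng.random(shape) < inner_prob
    cvm = np.broadcast_to(cv, shape)
    u = rng.uniform(-1.0, 1.0, shape) * cvm
    v = rng.uniform(1.0, 2.0, shape) * cvm
    s = np.where(rng.random(shape) < 0.5, -1.0, 1.0)
    return np.where(inner, 1.0 + u, 1.0 + s * v)


def perturb_dataset(
    dataset: CohortDataset,
    profile: CvProfile,
    seed: int | np.random.SeedSequence,
    exact_partition: bool = False,
) -> CohortDataset:
    """One perturbed copy of the dataset; metadata and mask unchanged."""
    rng = np.random.default_rng(seed)
    cv = profile.vector(list(dataset.schema.biomarkers))
    factors = perturbation_factors(dataset.values.shape, cv, rng, exact_partition=exact_partition)
    values = dataset.values * factors
    llod = dataset.schema.llod_vector()
    bad = values <= 0
    if bad.any():
        logger.warning("%d perturbed values were non-positive; clamped to LLoD", int(bad.sum()))
        values[bad] = np.broadcast_to(llod, values.shape)[bad]
    out = CohortDataset(dataset.schema, list(dataset.patients), values, np.zeros_like(dataset.imputed_mask))
    out.imputed_mask = dataset.imputed_mask.copy()  # carried metadata, not re-checked against LLoD
    return out


@dataclass
class PerturbationSummary:
    """Mean/min/max of each performance metric over the perturbed sets."""

    metrics: pd.DataFrame  # index: metric name; columns: mean, min, max
    per_set: pd.DataFrame  # one row per perturbed set
    n_sets: int

    def to_csv(self, path) -> None:
        self.metrics.to_csv(path, index_label="metric")


def perturbation_study(
    model,
    dataset: CohortDataset,
    profile: CvProfile,
    n_sets: int = 100,
    seed: int | np.random.SeedSequence = 0,
) -> PerturbationSummary:
    """Locked-classifier performance across ``n_sets`` perturbed datasets.

    For each perturbed copy the classifier is applied with its locked cutoff
    (no refitting) and AUC, specificity, and overall/stage I/stage II
    sensitivity are recorded; the summary reports mean/min/max per metric.
    """
    from .diagnostic_metrics import roc_curve
    from .model_development import apply_classifier

    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    labels = dataset.labels
    stages = dataset.stages
    if labels.min() == labels.max():
        raise ValueError("dataset must contain both classes")
    rows = []
    for k, child in enumerate(ss.spawn(n_sets)):
        perturbed = perturb_dataset(dataset, profile, child)
        scores, calls = apply_classifier(model, perturbed)
        roc = roc_curve(scores, labels)
        cases, controls = labels == 1, labels == 0
        row = {
            "set": k,
            "AUC": roc.auc,
            "specificity": float((~calls[controls]).mean()),
            "overall_sensitivity": float(calls[cases].mean()),
        }
        for stage, name in (("I", "stage1_sensitivity"), ("II", "stage2_sensitivity")):
            sel = cases & (stages == stage)
            if sel.any():
                row[name] = float(calls[sel].mean())
            else:
                warnings.warn(f"no stage {stage} cases; stage sensitivity omitted")
                row[name] = np.nan
        rows.append(row)
    per_set = pd.DataFrame(rows).set_index("set")
    metrics = pd.DataFrame({"mean": per_set.mean(), "min": per_set.min(), "max": per_set.max()})
    return PerturbationSummary(metrics=metrics, per_set=per_set, n_sets=n_sets)
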