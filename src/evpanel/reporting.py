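"""End-to-end pipeline driver and report generation.

``run_pipeline`` ties the stages together — cohort generation or loading,
reliability/redundancy filtering, cross-validated candidate selection,
recursive feature elimination, locking the logistic classifier with its
specificity-anchored cutoff, optional blinded-validation scoring, and the
measurement-noise perturbation study — and writes every artifact (locked
model JSON, CV report, importance table, ROC/cutoff table, fold-change
matrix, filter report, perturbation summary, run manifest, log) into one run
directory.  A single master seed fans out to named sub-streams
(plan / shuffle / perturb) recorded in the manifest, so a rerun with the
same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diagnostic_metrics import bootstrap_auc_ci, confusion_summary, roc_curve
from .feature_filters import FilterConfig, FilterReport, correlation_ks_filter, imputation_rate_filter
from .model_development import (
    CandidateSpec,
    default_candidates,
    evaluate_candidate,
    fit_locked_classifier,
    make_cv_plan,
    recursive_feature_elimination,
    apply_classifier,
)
from .panel_data import CohortDataset, PanelSchema, read_cohort
from .robustness import CvProfile, perturbation_study, within_patient_cv
from .synthetic_cohort import SyntheticConfig, generate_cohort, generate_replicates

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "FoldChangeMatrix", "run_pipeline", "fold_change_matrix"]


@dataclass
class PipelineConfig:
    """Everything needed for one reproducible run.

    Exactly one of (``synthetic``) or (``patients_path`` + ``measurements_path``
    + ``schema_path``) supplies the training cohort.
    """

    synthetic: SyntheticConfig | None = None
    patients_path: str | None = None
    measurements_path: str | None = None
    schema_path: str | None = None
    validation_synthetic: SyntheticConfig | None = None
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    candidates: list[CandidateSpec] = field(default_factory=default_candidates)
    n_reps: int = 100
    n_folds: int = 5
    n_target_features: int = 7
    target_specificity: float = 0.91
    perturbation_n_sets: int = 100
    bootstrap_reps: int = 2000
    master_seed: int = 0
    output_dir: str = "results/run"

    def __post_init__(self):
        real = self.patients_path is not None
        if real == (self.synthetic is not None):
            raise ValueError("exactly one of synthetic config or cohort file paths must be given")

    def digest(self) -> str:
        payload = repr(self).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class FoldChangeMatrix:
    """log2(group mean / control mean) per (group, biomarker).

    The control row is identically zero by construction.
    """

    frame: pd.DataFrame  # index: group; columns: biomarkers

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="group")


def fold_change_matrix(dataset: CohortDataset, by_stage: bool = True) -> FoldChangeMatrix:
    """Control-mean-normalized log2 fold changes per group."""
    labels = dataset.labels
    controls = labels == 0
    if not controls.any():
        raise ValueError("control group is empty")
    ref = dataset.values[controls].mean(axis=0)
    groups: dict[str, np.ndarray] = {"control": controls, "case": labels == 1}
    if by_stage:
        stages = dataset.stages
        for stage in ("I", "II"):
            sel = (labels == 1) & (stages == stage)
            if sel.any():
                groups[f"stage_{stage}"] = sel
    rows = {
        name: np.log2(dataset.values[sel].mean(axis=0) / ref)
        for name, sel in groups.items()
        if sel.any()
    }
    frame = pd.DataFrame(rows, index=list(dataset.schema.biomarkers)).T
    return FoldChangeMatrix(frame=frame)


def _cutoff_table(model, train_scores, train_labels, val_scores=None, val_labels=None) -> pd.DataFrame:
    """Every distinct training score as a candidate cutoff with its training
    (and validation) sensitivity/specificity."""
    rows = []
    for c in np.unique(train_scores):
        row = {
            "cutoff": c,
            "train_sensitivity": float((train_scores[train_labels == 1] >= c).mean()),
            "train_specificity": float((train_scores[train_labels == 0] < c).mean()),
        }
        if val_scores is not None:
            row["val_sensitivity"] = float((val_scores[val_labels == 1] >= c).mean())
            row["val_specificity"] = float((val_scores[val_labels == 0] < c).mean())
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages; returns the run directory.  Deterministic given config."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("evpanel")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    ss = np.random.SeedSequence(config.master_seed)
    plan_seed, shuffle_seed, perturb_seed, boot_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4))
    manifest: dict = {
        "config_hash": config.digest(),
        "evpanel_version": __version__,
        "master_seed": config.master_seed,
        "seeds": {"plan": plan_seed, "shuffle": shuffle_seed, "perturb": perturb_seed, "bootstrap": boot_seed},
        "stages": [],
    }
    try:
        # ---- stage: data -------------------------------------------------
        if config.synthetic is not None:
            cohort = generate_cohort(config.synthetic)
            replicates = generate_replicates(cohort, config.synthetic)
        else:
            schema = PanelSchema.from_yaml(config.schema_path)
            cohort = read_cohort(config.patients_path, config.measurements_path, schema)
            replicates = None
        logger.info("cohort: %d patients (%d cases), %d biomarkers",
                    cohort.n_patients, int(cohort.labels.sum()), cohort.schema.n_biomarkers)
        manifest["stages"].append({"stage": "data", "n_patients": cohort.n_patients,
                                   "n_biomarkers": cohort.schema.n_biomarkers})
        fold_change_matrix(cohort).to_csv(out / "fold_change.csv")

        # ---- stage: filter ----------------------------------------------
        report = FilterReport()
        kept = imputation_rate_filter(cohort, config.filter_config, report)
        logger.info("reliability filter: %d -> %d biomarkers", cohort.schema.n_biomarkers, len(kept))
        kept, removals = correlation_ks_filter(cohort, kept, cohort.labels, config.filter_config, report)
        logger.info("redundancy filter: removed %d, %d candidates remain", len(removals), len(kept))
        report.to_csv(out / "filter_report.csv")
        manifest["stages"].append({"stage": "filter", "n_candidates": len(kept),
                                   "n_removed_correlated": len(removals)})
        if len(kept) < config.n_target_features:
            raise RuntimeError("stage filter: fewer candidate features than panel size")

        # ---- stage: CV candidate selection ------------------------------
        filtered = cohort.subset_biomarkers(kept)
        plan = make_cv_plan(cohort.labels, config.n_reps, config.n_folds, plan_seed)
        summaries = []
        best = None
        best_importance = None
        for cand in config.candidates:
            want_imp = cand.algorithm == "logistic_regression"
            res, imp = evaluate_candidate(
                cand, filtered, plan, config.target_specificity,
                importance=want_imp, shuffle_seed=shuffle_seed,
            )
            summaries.append(res.summary())
            if best is None or res.mean_pauc > best[0].mean_pauc:
                best, best_importance = (res,), imp
        cv_report = pd.DataFrame(summaries).sort_values("mean_pauc", ascending=False)
        cv_report.to_csv(out / "cv_report.csv", index=False)
        if best_importance is not None:
            best_importance.to_csv(out / "importance.csv")
        chosen = best[0].candidate
        logger.info("selected candidate %s (mean pAUC %.4f)", chosen.name, best[0].mean_pauc)
        manifest["stages"].append({"stage": "cv_selection", "chosen": chosen.name,
                                   "mean_pauc": best[0].mean_pauc})

        # ---- stage: RFE + lock ------------------------------------------
        selected = recursive_feature_elimination(filtered, kept, config.n_target_features)
        model = fit_locked_classifier(cohort.subset_biomarkers(selected), selected, config.target_specificity)
        model.to_json(out / "locked_model.json")
        logger.info("locked model on %d features, cutoff %.4f", len(selected), model.cutoff)
        manifest["stages"].append({"stage": "lock", "features": selected, "cutoff": model.cutoff})

        # ---- stage: training / validation performance --------------------
        train_scores, train_calls = apply_classifier(model, cohort)
        summary = confusion_summary(train_calls, cohort.labels, cohort.stages)
        perf = summary.to_frame()
        perf.insert(0, "cohort", "training")
        auc_ci = bootstrap_auc_ci(train_scores, cohort.labels, config.bootstrap_reps, seed=boot_seed)
        val_scores = val_labels = None
        if config.validation_synthetic is not None:
            vcohort = generate_cohort(config.validation_synthetic)
            val_scores, val_calls = apply_classifier(model, vcohort)
            val_labels = vcohort.labels
            vsummary = confusion_summary(val_calls, val_labels, vcohort.stages).to_frame()
            vsummary.insert(0, "cohort", "validation")
            perf = pd.concat([perf, vsummary], ignore_index=True)
        perf.to_csv(out / "performance.csv", index=False)
        _cutoff_table(model, train_scores, cohort.labels, val_scores, val_labels).to_csv(
            out / "cutoff_table.csv", index=False
        )
        manifest["stages"].append({"stage": "validate",
                                   "training_auc": auc_ci.auc,
                                   "training_auc_ci": [auc_ci.lower, auc_ci.upper]})

        # ---- stage: perturbation ----------------------------------------
        if replicates is not None:
            profile = within_patient_cv(replicates)
        else:
            profile = CvProfile.constant(list(cohort.schema.biomarkers), 0.1)
            logger.info("no replicate data; perturbation uses a flat 10%% CV profile")
        study = perturbation_study(model, cohort, profile,
                                   n_sets=config.perturbation_n_sets,
                                   seed=np.random.SeedSequence(perturb_seed))
        study.to_csv(out / "perturbation_summary.csv")
        study.per_set.to_csv(out / "perturbation_per_set.csv")
        manifest["stages"].append({"stage": "perturb", "n_sets": study.n_sets})
    except Exception as e:
        manifest["error"] = f"stage failure: {e}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
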