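"""Classifier-development engine: repeated stratified cross-validation over
candidate pipelines with a partial-AUC objective, permutation feature
importance, recursive feature elimination, and the locked logistic classifier.

The protocol mirrors standard leakage-free biomarker-panel development:

- A CV plan of ``n_reps`` repetitions of ``n_folds``-fold cross-validation,
  stratified by the binary case/control response, is fixed up front from a
  seed, so every candidate sees identical folds.
- Within every fold, the reliability (imputation-rate) and redundancy
  (correlation + KS) filters and any transforms are fit on the training
  portion only and then applied to the held-out fold; held-out metrics
  (pAUC over the 90-100% specificity band, AUC, sensitivity at the target
  specificity) are averaged over all folds of all repetitions.
- Feature importance is model-agnostic permutation importance: per fold,
  each feature column of the held-out data is shuffled ten times and the
  average loss from the fold baselines in each metric is the feature's score.
- The final model is a logistic regression on log2-transformed
  concentrations restricted by recursive feature elimination to a fixed
  panel size (default 7), with the decision cutoff locked at the score
  achieving the target specificity (default 91%) on the training controls.

Scores live in (0, 1) (the sigmoid output); a sample is called positive when
its score >= the locked cutoff, and applying a locked model never refits
anything.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .diagnostic_metrics import partial_auc, roc_curve, threshold_for_specificity
from .feature_filters import FilterConfig, correlation_ks_filter, imputation_rate_filter
from .panel_data import CohortDataset

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateSpec",
    "CvPlan",
    "CvResult",
    "ImportanceTable",
    "TrainedClassifier",
    "default_candidates",
    "make_cv_plan",
    "evaluate_candidate",
    "permutation_importance",
    "recursive_feature_elimination",
    "fit_locked_classifier",
    "apply_classifier",
]

SPEC_BAND_MIN = 0.90  # pAUC band: specificities 90-100%


# ---------------------------------------------------------------------------
# candidate registry

def _make_logistic(hp: dict) -> LogisticRegression:
    return LogisticRegression(C=hp.get("C", 1.0), solver="lbfgs", max_iter=5000)


def _make_random_forest(hp: dict) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=hp.get("n_estimators", 200),
        max_depth=hp.get("max_depth"),
        random_state=hp.get("random_state", 0),
    )


def _make_gbt(hp: dict) -> GradientBoostingClassifier:
    return GradientBoostingClassifier(
        n_estimators=hp.get("n_estimators", 100),
        learning_rate=hp.get("learning_rate", 0.1),
        max_depth=hp.get("max_depth", 3),
        random_state=hp.get("random_state", 0),
    )


def _make_svm(hp: dict) -> SVC:
    return SVC(C=hp.get("C", 1.0), kernel=hp.get("kernel", "rbf"), probability=False)


def _make_neural_net(hp: dict):
    # registry stub: the family is registered but no estimator is shipped
    raise NotImplementedError("neural_net candidate is a registry stub")


ALGORITHMS: dict[str, Callable] = {
    "logistic_regression": _make_logistic,
    "random_forest": _make_random_forest,
    "gradient_boosted_trees": _make_gbt,
    "svm": _make_svm,
    "neural_net": _make_neural_net,
}

TRANSFORMS = ("log2", "standardize", "none", "composed")


@dataclass(frozen=True)
class CandidateSpec:
    """One point of the candidate grid: algorithm x transform x
    hyperparameters x filter settings."""

    algorithm: str
    transform: str = "log2"
    hyperparameters: tuple = ()
    filter_config: FilterConfig = FilterConfig()
    name: str = ""

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if isinstance(self.hyperparameters, dict):
            object.__setattr__(self, "hyperparameters", tuple(sorted(self.hyperparameters.items())))
        if not self.name:
            object.__setattr__(self, "name", f"{self.algorithm}:{self.transform}")

    @property
    def hp(self) -> dict:
        return dict(self.hyperparameters)

    def make_estimator(self):
        return ALGORITHMS[self.algorithm](self.hp)


def default_candidates() -> list[CandidateSpec]:
    """The shipped default grid: regularized logistic regression plus small
    random-forest and gradient-boosting grids."""
    out = [
        CandidateSpec("logistic_regression", "log2", {"C": c}, name=f"logistic_log2_C{c}")
        for c in (0.1, 1.0, 10.0)
    ]
    out.append(CandidateSpec("random_forest", "none", {"n_estimators": 200}, name="rf_200"))
    out.append(CandidateSpec("gradient_boosted_trees", "none", {"n_estimators": 100}, name="gbt_100"))
    return out


def _transform(X: np.ndarray, transform: str, scaler: StandardScaler | None = None):
    """Apply the candidate's transform; returns (X_t, fitted scaler or None)."""
    if transform == "none":
        return X, None
    if transform == "log2":
        return np.log2(X), None
    if transform == "standardize":
        if scaler is None:
            scaler = StandardScaler().fit(X)
        return scaler.transform(X), scaler
    if transform == "composed":  # log2 then standardize
        Xl = np.log2(X)
        if scaler is None:
            scaler = StandardScaler().fit(Xl)
        return scaler.transform(Xl), scaler
    raise ValueError(transform)


def _sigmoid(lin: np.ndarray) -> np.ndarray:
    """Sigmoid clipped to the open interval (0, 1) at float resolution."""
    with np.errstate(over="ignore"):
        s = 1.0 / (1.0 + np.exp(-np.asarray(lin, float)))
    return np.clip(s, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))


def _scores(est, X: np.ndarray) -> np.ndarray:
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    return est.decision_function(X)


# ---------------------------------------------------------------------------
# cross-validation plan

@dataclass
class CvPlan:
    """Fold assignments for repeated stratified cross-validation.

    ``fold_of[r, i]`` is the validation fold (0..n_folds-1) of patient i in
    repetition r.  Every repetition partitions all patients; per-fold case
    counts differ from perfect balance by at most one patient.
    """

    n_reps: int
    n_folds: int
    seed: int
    fold_of: np.ndarray

    def splits(self):
        """Yield (rep, fold, train_idx, val_idx) over all rep x fold pairs."""
        for r in range(self.n_reps):
            for f in range(self.n_folds):
                val = np.nonzero(self.fold_of[r] == f)[0]
                train = np.nonzero(self.fold_of[r] != f)[0]
                yield r, f, train, val


def make_cv_plan(labels: np.ndarray, n_reps: int = 100, n_folds: int = 5, seed: int = 0) -> CvPlan:
    """Repeated stratified k-fold plan, deterministic given the seed."""
    labels = np.asarray(labels).astype(int)
    for cls in (0, 1):
        if (labels == cls).sum() < n_folds:
            raise ValueError(f"class {cls} has fewer than {n_folds} patients")
    rng = np.random.default_rng(seed)
    fold_of = np.empty((n_reps, labels.size), dtype=np.int8)
    for r in range(n_reps):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31)))
        for f, (_, val) in enumerate(skf.split(np.zeros(labels.size), labels)):
            fold_of[r, val] = f
    return CvPlan(n_reps=n_reps, n_folds=n_folds, seed=seed, fold_of=fold_of)


# ---------------------------------------------------------------------------
# candidate evaluation

@dataclass
class CvResult:
    """Mean and dispersion of held-out metrics over all folds of all reps."""

    candidate: CandidateSpec
    per_fold: pd.DataFrame  # columns: rep, fold, pauc, auc, sensitivity, n_features
    n_failed_folds: int = 0

    @property
    def mean_pauc(self) -> float:
        return float(self.per_fold["pauc"].mean())

    @property
    def mean_auc(self) -> float:
        return float(self.per_fold["auc"].mean())

    @property
    def mean_sensitivity(self) -> float:
        return float(self.per_fold["sensitivity"].mean())

    def summary(self) -> dict:
        return {
            "candidate": self.candidate.name,
            "mean_pauc": self.mean_pauc,
            "sd_pauc": float(self.per_fold["pauc"].std(ddof=1)),
            "mean_auc": self.mean_auc,
            "mean_sensitivity": self.mean_sensitivity,
            "n_folds": len(self.per_fold),
            "n_failed_folds": self.n_failed_folds,
        }


@dataclass
class ImportanceTable:
    """Mean permutation loss per feature in pAUC, AUC and sensitivity."""

    table: pd.DataFrame  # index: feature; columns: loss_pauc, loss_auc, loss_sensitivity, n_folds
    n_shuffles: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="feature")


def _fold_metrics(scores: np.ndarray, labels: np.ndarray, cutoff: float,
                  target_specificity: float) -> tuple[float, float, float]:
    roc = roc_curve(scores, labels)
    sens = float((scores[labels == 1] >= cutoff).mean())
    return partial_auc(roc, SPEC_BAND_MIN), roc.auc, sens


def evaluate_candidate(
    spec: CandidateSpec,
    dataset: CohortDataset,
    plan: CvPlan,
    target_specificity: float = 0.91,
    importance: bool = False,
    n_shuffles: int = 10,
    shuffle_seed: int = 0,
) -> tuple[CvResult, ImportanceTable | None]:
    """Held-out performance of one candidate under the fixed CV plan.

    Filters and transforms are fit on each fold's training portion only,
    then applied to the held-out fold: the held-out patients never influence
    feature selection, scaling, the model fit, or the fold-level cutoff used
    for the sensitivity metric (set at ``target_specificity`` on the training
    controls).  Folds whose filters remove every feature are recorded as
    failed and flagged.
    """
    labels = dataset.labels
    rows = []
    n_failed = 0
    imp_acc: dict[str, np.ndarray] = {}
    imp_folds = 0
    shuffle_rng = np.random.default_rng(shuffle_seed)
    for rep, fold, train_idx, val_idx in plan.splits():
        train = dataset.subset_patients(train_idx)
        kept = imputation_rate_filter(train, spec.filter_config)
        if len(kept) >= 2:
            kept, _ = correlation_ks_filter(train, kept, train.labels, spec.filter_config)
        if not kept:
            logger.warning("candidate %s rep %d fold %d: filters removed all features", spec.name, rep, fold)
            n_failed += 1
            continue
        cols = [dataset.biomarker_index(b) for b in kept]
        X_train, scaler = _transform(dataset.values[np.ix_(train_idx, cols)], spec.transform)
        X_val, _ = _transform(dataset.values[np.ix_(val_idx, cols)], spec.transform, scaler)
        y_train, y_val = labels[train_idx], labels[val_idx]
        est = spec.make_estimator().fit(X_train, y_train)
        cutoff = threshold_for_specificity(_scores(est, X_train)[y_train == 0], target_specificity)
        s_val = _scores(est, X_val)
        pauc, auc, sens = _fold_metrics(s_val, y_val, cutoff, target_specificity)
        rows.append({"rep": rep, "fold": fold, "pauc": pauc, "auc": auc,
                     "sensitivity": sens, "n_features": len(kept)})
        if importance:
            baselines = {"pauc": pauc, "auc": auc, "sensitivity": sens}
            losses = permutation_importance(
                est, X_val, y_val, kept, baselines, cutoff,
                n_shuffles=n_shuffles, seed=int(shuffle_rng.integers(2**31)),
            )
            for feat, trio in losses.items():
                imp_acc.setdefault(feat, np.zeros(4))
                imp_acc[feat][:3] += trio
                imp_acc[feat][3] += 1
            imp_folds += 1
    result = CvResult(candidate=spec, per_fold=pd.DataFrame(rows), n_failed_folds=n_failed)
    table = None
    if importance and imp_acc:
        records = {
            feat: {
                "loss_pauc": acc[0] / acc[3],
                "loss_auc": acc[1] / acc[3],
                "loss_sensitivity": acc[2] / acc[3],
                "n_folds": int(acc[3]),
            }
            for feat, acc in imp_acc.items()
        }
        table = ImportanceTable(pd.DataFrame(records).T.sort_values("loss_pauc", ascending=False),
                                n_shuffles=n_shuffles)
    return result, table


def permutation_importance(
    model,
    X_val: np.ndarray,
    y_val: np.ndarray,
    feature_names: list[str],
    baselines: dict[str, float],
    cutoff: float,
    n_shuffles: int = 10,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Average loss from baseline after shuffling each held-out feature.

    Per feature: the column is shuffled ``n_shuffles`` times across all
    held-out observations and the mean drop in pAUC, AUC and sensitivity
    (at the fold's locked cutoff) is returned.  Higher loss means the model
    relies more on that feature.
    """
    if X_val.shape[0] < 2:
        raise ValueError("held-out fold must contain more than one patient")
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for j, feat in enumerate(feature_names):
        losses = np.zeros(3)
        for _ in range(n_shuffles):
            Xp = X_val.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            s = _scores(model, Xp)
            pauc, auc, sens = _fold_metrics(s, y_val, cutoff, 0.91)
            losses += [baselines["pauc"] - pauc, baselines["auc"] - auc, baselines["sensitivity"] - sens]
        out[feat] = losses / n_shuffles
    return out


# ---------------------------------------------------------------------------
# RFE + locked model

def recursive_feature_elimination(
    dataset: CohortDataset,
    candidate_features: list[str],
    n_target: int = 7,
    plan: CvPlan | None = None,
) -> list[str]:
    """Reduce to ``n_target`` features by iterated logistic refits.

    At each step a logistic regression is fit on log2-transformed,
    internally standardized features (standardization is for coefficient
    ranking only) and the feature with the smallest absolute standardized
    coefficient is dropped.  Returns the survivors in schema order.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    if len(candidate_features) < n_target:
        raise ValueError("fewer candidate features than n_target")
    features = list(candidate_features)
    y = dataset.labels
    while len(features) > n_target:
        X = np.log2(np.column_stack([dataset.column(b) for b in features]))
        Xs = StandardScaler().fit_transform(X)
        est = LogisticRegression(C=1.0, solver="lbfgs", max_iter=5000).fit(Xs, y)
        weakest = int(np.argmin(np.abs(est.coef_[0])))
        features.pop(weakest)
    return features


@dataclass
class TrainedClassifier:
    """Locked logistic classifier on log2 concentrations.

    score = sigmoid(intercept + sum_i coef_i * log2(x_i)); a sample is
    called positive when score >= cutoff.  All fields are frozen at training
    time; applying the model never refits or rescales anything.
    """

    selected_features: list[str]
    coefficients: dict[str, float]
    intercept: float
    cutoff: float
    target_specificity: float = 0.91
    transform: str = "log2"
    ridge_fallback: bool = False

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {
                "selected_features": self.selected_features,
                "transform": self.transform,
                "coefficients": self.coefficients,
                "intercept": self.intercept,
                "cutoff": self.cutoff,
                "target_specificity": self.target_specificity,
                "ridge_fallback": self.ridge_fallback,
            },
            indent=1,
        ))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedClassifier":
        d = json.loads(Path(path).read_text())
        return cls(
            selected_features=d["selected_features"],
            coefficients=d["coefficients"],
            intercept=d["intercept"],
            cutoff=d["cutoff"],
            target_specificity=d["target_specificity"],
            transform=d.get("transform", "log2"),
            ridge_fallback=d.get("ridge_fallback", False),
        )


def fit_locked_classifier(
    dataset: CohortDataset,
    features: list[str],
    target_specificity: float = 0.91,
) -> TrainedClassifier:
    """Fit the final logistic model and lock the cutoff on training controls.

    The cutoff is the smallest score achieving the target specificity among
    the training controls, then fixed for all later applications.  Under
    perfect separation the unpenalized fit diverges; the model falls back to
    a ridge (L2) penalized fit and records that it did.
    """
    y = dataset.labels
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    X = np.log2(np.column_stack([dataset.column(b) for b in features]))
    import warnings as _warnings
    from sklearn.exceptions import ConvergenceWarning

    ridge = False
    with _warnings.catch_warnings():
        # separation makes the unpenalized likelihood unbounded; the fit then
        # hits max_iter with huge coefficients and we fall back to ridge below
        _warnings.simplefilter("ignore", ConvergenceWarning)
        est = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000).fit(X, y)
    if not np.all(np.isfinite(est.coef_)) or np.abs(est.coef_).max() > 1e3:
        logger.warning("apparent separation in unpenalized fit; using ridge-penalized fallback")
        est = LogisticRegression(C=1.0, solver="lbfgs", max_iter=5000).fit(X, y)
        ridge = True
    coefs = {f: float(c) for f, c in zip(features, est.coef_[0])}
    intercept = float(est.intercept_[0])
    scores = _sigmoid(X @ est.coef_[0] + intercept)
    cutoff = threshold_for_specificity(scores[y == 0], target_specificity)
    return TrainedClassifier(
        selected_features=list(features),
        coefficients=coefs,
        intercept=intercept,
        cutoff=float(cutoff),
        target_specificity=target_specificity,
        ridge_fallback=ridge,
    )


def apply_classifier(model: TrainedClassifier, dataset: CohortDataset) -> tuple[np.ndarray, np.ndarray]:
    """Score a cohort with a locked model: returns (scores, positive calls)."""
    missing = [f for f in model.selected_features if f not in dataset.schema.biomarkers]
    if missing:
        raise KeyError(f"dataset missing selected features: {missing}")
    X = np.log2(np.column_stack([dataset.column(b) for b in model.selected_features]))
    w = np.array([model.coefficients[f] for f in model.selected_features])
    scores = _sigmoid(X @ w + model.intercept)
    return scores, scores >= model.cutoff
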