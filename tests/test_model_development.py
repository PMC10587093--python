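"""CV plan stratification, leakage-free candidate evaluation, permutation
importance, RFE, and the locked logistic classifier."""

import numpy as np
import pytest

from evpanel.diagnostic_metrics import roc_curve, threshold_for_specificity
from evpanel.model_development import (
    CandidateSpec,
    apply_classifier,
    evaluate_candidate,
    fit_locked_classifier,
    make_cv_plan,
    permutation_importance,
    recursive_feature_elimination,
)
from evpanel.synthetic_cohort import SyntheticConfig, generate_cohort

from conftest import make_dataset


def strong_cohort(seed=0, n_noise=27, shifts=(3.0, 2.5, 2.0, 2.0, 1.5, 1.5, 1.5)):
    cfg = SyntheticConfig(
        n_cases_stage1=39, n_cases_stage2=66, n_controls=545,
        n_biomarkers=len(shifts) + n_noise,
        informative_set={i: s for i, s in enumerate(shifts)},
        seed=seed,
    )
    return generate_cohort(cfg)


class TestMakeCvPlan:
    def test_exact_divisibility_perfect_balance(self):
        labels = np.r_[np.ones(10, int), np.zeros(10, int)]
        plan = make_cv_plan(labels, n_reps=3, n_folds=5, seed=0)
        for r in range(3):
            for f in range(5):
                fold = plan.fold_of[r] == f
                assert labels[fold].sum() == 2 and (~labels.astype(bool))[fold].sum() == 2

    def test_study_scale_fold_counts(self):
        labels = np.r_[np.ones(105, int), np.zeros(545, int)]
        plan = make_cv_plan(labels, n_reps=2, n_folds=5, seed=1)
        for r in range(2):
            for f in range(5):
                fold = plan.fold_of[r] == f
                assert labels[fold].sum() == 21
                assert (labels[fold] == 0).sum() == 109

    def test_each_patient_in_exactly_one_validation_fold(self):
        labels = np.r_[np.ones(13, int), np.zeros(29, int)]
        plan = make_cv_plan(labels, n_reps=4, n_folds=5, seed=2)
        assert plan.fold_of.shape == (4, 42)
        assert set(np.unique(plan.fold_of)) == set(range(5))

    def test_same_seed_identical_plan(self):
        labels = np.r_[np.ones(20, int), np.zeros(30, int)]
        a = make_cv_plan(labels, 5, 5, seed=3)
        b = make_cv_plan(labels, 5, 5, seed=3)
        assert np.array_equal(a.fold_of, b.fold_of)

    def test_class_smaller_than_folds_rejected(self):
        labels = np.r_[np.ones(3, int), np.zeros(30, int)]
        with pytest.raises(ValueError):
            make_cv_plan(labels, 1, 5, seed=0)


class TestEvaluateCandidate:
    def test_strong_markers_yield_high_held_out_auc(self):
        d = strong_cohort(seed=1)
        plan = make_cv_plan(d.labels, n_reps=1, n_folds=5, seed=0)
        res, _ = evaluate_candidate(CandidateSpec("logistic_regression"), d, plan)
        assert res.mean_auc > 0.95
        assert res.n_failed_folds == 0

    def test_deterministic_given_plan(self):
        d = strong_cohort(seed=2, n_noise=5)
        plan = make_cv_plan(d.labels, n_reps=1, n_folds=5, seed=0)
        spec = CandidateSpec("logistic_regression")
        a, _ = evaluate_candidate(spec, d, plan)
        b, _ = evaluate_candidate(spec, d, plan)
        assert a.per_fold.equals(b.per_fold)

    def test_label_permutation_gives_chance_pauc(self):
        # leakage guard: with labels shuffled, the full in-fold pipeline
        # (filters + fit) must not beat chance pAUC (0.005)
        d = strong_cohort(seed=3, n_noise=10)
        rng = np.random.default_rng(0)
        permuted = make_dataset(d.values, rng.permutation(d.labels),
                                llod=d.schema.llod_vector())
        plan = make_cv_plan(permuted.labels, n_reps=2, n_folds=5, seed=0)
        res, _ = evaluate_candidate(CandidateSpec("logistic_regression"), permuted, plan)
        se = res.per_fold["pauc"].std(ddof=1) / np.sqrt(len(res.per_fold))
        assert abs(res.mean_pauc - 0.005) <= 3 * se + 1e-9


class TestPermutationImportance:
    def test_ignored_feature_has_zero_loss(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 2))
        y = (X[:, 0] > 0).astype(int)

        class Stub:
            def decision_function(self, X):
                return X[:, 0]  # coefficient 0 on feature 1

        base_roc = roc_curve(X[:, 0], y)
        cutoff = threshold_for_specificity(X[y == 0, 0], 0.91)
        from evpanel.diagnostic_metrics import partial_auc

        baselines = {"pauc": partial_auc(base_roc), "auc": base_roc.auc,
                     "sensitivity": float((X[y == 1, 0] >= cutoff).mean())}
        losses = permutation_importance(Stub(), X, y, ["f0", "f1"], baselines, cutoff, seed=1)
        assert np.allclose(losses["f1"], 0.0)
        assert losses["f0"][1] > 0.3  # shuffling the only real feature hurts

    def test_single_feature_shuffle_destroys_signal(self):
        # AUC loss ~ baseline AUC - 0.5 when the sole feature is shuffled
        rng = np.random.default_rng(1)
        n = 400
        y = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        X = (rng.normal(size=n) + 2.2 * y).reshape(-1, 1)

        class Stub:
            def decision_function(self, X):
                return X[:, 0]

        roc = roc_curve(X[:, 0], y)
        cutoff = threshold_for_specificity(X[y == 0, 0], 0.91)
        baselines = {"pauc": 0.0, "auc": roc.auc, "sensitivity": 0.0}
        losses = permutation_importance(Stub(), X, y, ["f0"], baselines, cutoff,
                                        n_shuffles=10, seed=2)
        assert losses["f0"][1] == pytest.approx(roc.auc - 0.5, abs=0.05)

    def test_fixed_seed_identical(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 3))
        y = (X[:, 0] + 0.5 * X[:, 1] > 0).astype(int)

        class Stub:
            def decision_function(self, X):
                return X[:, 0] + 0.5 * X[:, 1]

        baselines = {"pauc": 0.05, "auc": 0.9, "sensitivity": 0.8}
        a = permutation_importance(Stub(), X, y, list("abc"), baselines, 0.5, seed=9)
        b = permutation_importance(Stub(), X, y, list("abc"), baselines, 0.5, seed=9)
        assert all(np.array_equal(a[k], b[k]) for k in a)


class TestRecursiveFeatureElimination:
    def test_n_target_equal_to_candidates_is_identity(self):
        d = strong_cohort(seed=4, n_noise=0)
        names = list(d.schema.biomarkers)
        assert recursive_feature_elimination(d, names, n_target=7) == names

    def test_recovers_planted_informative_markers(self):
        d = strong_cohort(seed=5)
        kept = recursive_feature_elimination(d, list(d.schema.biomarkers), 7)
        informative = {f"BM{j:02d}" for j in range(7)}
        assert len(informative & set(kept)) >= 6

    def test_duplicated_informative_pair_keeps_exactly_one(self):
        rng = np.random.default_rng(6)
        labels = np.r_[np.ones(60, int), np.zeros(140, int)]
        sig = np.exp2(rng.normal(5, 1, 200) + 2.5 * labels)
        other = [np.exp2(rng.normal(5, 1, 200) + s * labels) for s in (2.0, 1.5, 0, 0, 0, 0, 0)]
        values = np.column_stack([sig, sig, *other])
        d = make_dataset(values, labels)
        kept = recursive_feature_elimination(d, list(d.schema.biomarkers), 3)
        assert ("M0" in kept) != ("M1" in kept)

    def test_invalid_target_rejected(self):
        d = strong_cohort(seed=7, n_noise=0)
        with pytest.raises(ValueError):
            recursive_feature_elimination(d, list(d.schema.biomarkers), 0)


class TestLockedClassifier:
    def test_cutoff_achieves_target_specificity_on_training_controls(self):
        d = strong_cohort(seed=8, n_noise=3)
        feats = [f"BM{j:02d}" for j in range(7)]
        model = fit_locked_classifier(d, feats)
        scores, calls = apply_classifier(model, d)
        controls = d.labels == 0
        assert (~calls[controls]).mean() >= 0.91

    def test_scores_strictly_inside_unit_interval(self):
        d = strong_cohort(seed=9, n_noise=0)
        model = fit_locked_classifier(d, list(d.schema.biomarkers))
        scores, _ = apply_classifier(model, d)
        assert np.all(scores > 0) and np.all(scores < 1)

    def test_separable_data_full_training_sensitivity_with_ridge_fallback(self):
        rng = np.random.default_rng(10)
        labels = np.r_[np.ones(30, int), np.zeros(70, int)]
        x = np.exp2(rng.normal(3, 0.3, 100) + 10 * labels)  # fully separable
        d = make_dataset(x.reshape(-1, 1), labels)
        model = fit_locked_classifier(d, ["M0"])
        _, calls = apply_classifier(model, d)
        assert calls[d.labels == 1].all()

    def test_apply_is_pure_and_repeatable(self):
        d = strong_cohort(seed=11, n_noise=2)
        model = fit_locked_classifier(d, [f"BM{j:02d}" for j in range(7)])
        s1, c1 = apply_classifier(model, d)
        s2, c2 = apply_classifier(model, d)
        assert np.array_equal(s1, s2) and np.array_equal(c1, c2)

    def test_doubling_concentration_shifts_linear_predictor_by_coefficient(self):
        d = strong_cohort(seed=12, n_noise=0)
        feats = [f"BM{j:02d}" for j in range(7)]
        model = fit_locked_classifier(d, feats)
        s1, _ = apply_classifier(model, d)
        from evpanel.panel_data import CohortDataset

        doubled = CohortDataset(d.schema, d.patients,
                                d.values * np.where(np.arange(7) == 0, 2.0, 1.0))
        s2, _ = apply_classifier(model, doubled)
        lin1 = np.log(s1 / (1 - s1))
        lin2 = np.log(s2 / (1 - s2))
        # keep clear of sigmoid saturation, where log-odds lose resolution
        ok = (np.abs(lin1) < 25) & (np.abs(lin2) < 25)
        assert ok.sum() > 20
        assert np.allclose((lin2 - lin1)[ok], model.coefficients[feats[0]], atol=1e-6)

    def test_missing_feature_column_rejected(self):
        d = strong_cohort(seed=13, n_noise=0)
        model = fit_locked_classifier(d, [f"BM{j:02d}" for j in range(7)])
        reduced = d.subset_biomarkers([f"BM{j:02d}" for j in range(6)])
        with pytest.raises(KeyError):
            apply_classifier(model, reduced)

    def test_generalizes_to_matched_validation_cohort(self):
        train = strong_cohort(seed=14)
        val = strong_cohort(seed=15)
        feats = recursive_feature_elimination(train, list(train.schema.biomarkers), 7)
        model = fit_locked_classifier(train, feats)
        _, calls_t = apply_classifier(model, train)
        _, calls_v = apply_classifier(model, val)
        for sel_t, sel_v, n in [
            (train.labels == 1, val.labels == 1, 105),
            (train.labels == 0, val.labels == 0, 545),
        ]:
            pt, pv = calls_t[sel_t].mean(), calls_v[sel_v].mean()
            se = np.sqrt(max(pt * (1 - pt), 0.25 / n) / n)
            assert abs(pv - pt) <= 3 * se + 0.03
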