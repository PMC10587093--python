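"""ROC/AUC, partial AUC, Wilson and bootstrap intervals, threshold rule."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from evpanel.diagnostic_metrics import (
    bootstrap_auc_ci,
    confusion_summary,
    partial_auc,
    roc_curve,
    threshold_for_specificity,
    wilson_interval,
)


def auc_brute(scores, labels):
    """Pairwise concordance with ties counting 1/2 (independent oracle)."""
    scores = np.asarray(scores, float)
    cases = scores[np.asarray(labels) == 1]
    controls = scores[np.asarray(labels) == 0]
    total = 0.0
    for c in cases:
        for u in controls:
            total += 1.0 if c > u else (0.5 if c == u else 0.0)
    return total / (len(cases) * len(controls))


class TestRocCurve:
    def test_perfect_separation(self):
        roc = roc_curve([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert roc.auc == 1.0

    def test_all_ties_is_chance(self):
        roc = roc_curve([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert roc.auc == 0.5

    def test_three_by_three_example(self):
        # 8 of 9 case-control pairs concordant
        scores = [0.9, 0.8, 0.4, 0.7, 0.3, 0.2]
        labels = [1, 1, 1, 0, 0, 0]
        assert auc_brute(scores, labels) == pytest.approx(8 / 9)
        assert roc_curve(scores, labels).auc == pytest.approx(8 / 9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.2], [1, 1])

    def test_monotone_staircase_with_endpoints(self):
        rng = np.random.default_rng(0)
        roc = roc_curve(rng.random(40), np.r_[np.ones(15, int), np.zeros(25, int)])
        assert np.all(np.diff(roc.sensitivity) <= 0)  # thresholds ascending
        assert np.all(np.diff(roc.specificity) >= 0)
        assert roc.sensitivity[0] == 1 and roc.specificity[0] == 0
        assert roc.sensitivity[-1] == 0 and roc.specificity[-1] == 1

    def test_auc_matches_rank_sum_oracle_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = rng.integers(4, 50)
            labels = np.zeros(n, int)
            labels[: rng.integers(1, n)] = 1
            scores = rng.choice([0.1, 0.25, 0.5, 0.8], size=n)  # many ties
            assert roc_curve(scores, labels).auc == pytest.approx(auc_brute(scores, labels))


class TestPartialAuc:
    def test_perfect_classifier_equals_band_width(self):
        roc = roc_curve([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert partial_auc(roc, 0.9) == pytest.approx(0.10)

    def test_chance_diagonal_triangle_area(self):
        # all scores tied -> ROC is the diagonal; area 0.1^2 / 2
        roc = roc_curve([0.5] * 20, [1] * 10 + [0] * 10)
        assert partial_auc(roc, 0.9) == pytest.approx(0.005)

    def test_hand_integrated_step_example(self):
        # step ROC of the 3x3 example: TPR = 2/3 over FPR in [0, 1/3]
        roc = roc_curve([0.9, 0.8, 0.4, 0.7, 0.3, 0.2], [1, 1, 1, 0, 0, 0])
        assert partial_auc(roc, 0.9) == pytest.approx(0.1 * 2 / 3)

    def test_spec_min_zero_recovers_full_auc(self):
        rng = np.random.default_rng(2)
        scores = rng.random(60)
        labels = np.r_[np.ones(20, int), np.zeros(40, int)]
        roc = roc_curve(scores, labels)
        assert partial_auc(roc, 0.0) == pytest.approx(roc.auc)

    def test_invalid_band_rejected(self):
        roc = roc_curve([0.9, 0.1], [1, 0])
        with pytest.raises(ValueError):
            partial_auc(roc, 1.0)


class TestWilsonInterval:
    # printed two-sided 95% Wilson bounds for diagnostic-performance tables
    @pytest.mark.parametrize(
        "s,n,lo,hi",
        [
            (27, 30, 74.4, 96.5),
            (10, 10, 72.2, 100.0),
            (17, 20, 64.0, 94.8),
            (77, 83, 85.1, 96.6),
        ],
    )
    def test_published_style_bounds(self, s, n, lo, hi):
        ci = wilson_interval(s, n)
        assert round(100 * ci.lower, 1) == lo
        assert round(100 * ci.upper, 1) == hi

    def test_zero_successes_lower_bound_zero(self):
        ci = wilson_interval(0, 10)
        assert ci.lower == 0.0

    def test_all_successes_upper_bound_one(self):
        assert wilson_interval(10, 10).upper == 1.0

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            wilson_interval(0, 0)

    @given(st.integers(0, 50), st.integers(1, 50))
    def test_reflection_equivariance(self, s, n):
        s = min(s, n)
        ci = wilson_interval(s, n)
        refl = wilson_interval(n - s, n)
        assert ci.lower == pytest.approx(1 - refl.upper, abs=1e-12)
        assert ci.upper == pytest.approx(1 - refl.lower, abs=1e-12)
        assert ci.lower <= s / n <= ci.upper


class TestBootstrapAucCi:
    def test_perfect_separation_degenerate_interval(self):
        scores = [0.9, 0.95, 0.1, 0.2, 0.05]
        labels = [1, 1, 0, 0, 0]
        ci = bootstrap_auc_ci(scores, labels, n_reps=100, seed=0)
        assert ci.lower == ci.upper == ci.auc == 1.0

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(3)
        scores = rng.random(80)
        labels = np.r_[np.ones(30, int), np.zeros(50, int)]
        a = bootstrap_auc_ci(scores, labels, n_reps=300, seed=7)
        b = bootstrap_auc_ci(scores, labels, n_reps=300, seed=7)
        assert a == b

    def test_interval_covers_point_and_shrinks_with_n(self):
        def width(n, seed):
            rng = np.random.default_rng(seed)
            cases = rng.normal(1.19, 1, n)  # true AUC ~ 0.8
            controls = rng.normal(0, 1, n)
            scores = np.r_[cases, controls]
            labels = np.r_[np.ones(n, int), np.zeros(n, int)]
            ci = bootstrap_auc_ci(scores, labels, n_reps=400, seed=seed)
            assert ci.lower <= ci.auc <= ci.upper
            return ci.upper - ci.lower

        w200 = np.mean([width(200, s) for s in range(5)])
        w800 = np.mean([width(800, s) for s in range(5)])
        assert w800 == pytest.approx(w200 / 2, rel=0.35)  # ~1/sqrt(4)


class TestThresholdForSpecificity:
    def test_enumerated_grid_hits_target_exactly(self):
        controls = np.arange(100) / 100.0
        cutoff = threshold_for_specificity(controls, 0.91)
        positives = (controls >= cutoff).sum()
        assert positives == 9
        assert (controls < cutoff).mean() == 0.91
        # brute-force: no smaller observed cutoff reaches the target
        for c in np.unique(controls):
            if c < cutoff:
                assert (controls < c).mean() < 0.91

    def test_target_one_yields_zero_false_positives(self):
        controls = np.array([0.1, 0.5, 0.9])
        cutoff = threshold_for_specificity(controls, 1.0)
        assert (controls >= cutoff).sum() == 0

    def test_degenerate_all_tied_scores(self):
        controls = np.full(10, 0.42)
        cutoff = threshold_for_specificity(controls, 0.91)
        achieved = (controls < cutoff).mean()
        assert achieved in (0.0, 1.0)

    @given(st.lists(st.floats(0.001, 0.999), min_size=1, max_size=60),
           st.floats(0.05, 1.0))
    def test_achieved_specificity_meets_target_in_sample(self, controls, target):
        controls = np.asarray(controls)
        cutoff = threshold_for_specificity(controls, target)
        assert (controls < cutoff).mean() >= target


class TestConfusionSummary:
    def test_validation_style_counts(self):
        # 27/30 cases called positive, 77/83 controls negative
        calls = np.r_[np.ones(27), np.zeros(3), np.zeros(77), np.ones(6)].astype(bool)
        labels = np.r_[np.ones(30, int), np.zeros(83, int)]
        s = confusion_summary(calls, labels)
        assert s.sensitivity.as_percent() == (90.0, 74.4, 96.5)
        assert s.specificity.as_percent() == (92.8, 85.1, 96.6)

    def test_all_positive_calls(self):
        calls = np.ones(10, bool)
        labels = np.r_[np.ones(4, int), np.zeros(6, int)]
        s = confusion_summary(calls, labels)
        assert s.sensitivity.proportion == 1.0
        assert s.specificity.proportion == 0.0

    def test_stage_subset_sensitivity(self):
        labels = np.r_[np.ones(30, int), np.zeros(5, int)]
        stages = np.array(["I"] * 10 + ["II"] * 20 + ["none"] * 5)
        calls = np.r_[np.ones(10), np.ones(17), np.zeros(3), np.zeros(5)].astype(bool)
        s = confusion_summary(calls, labels, stages)
        assert s.stage_sensitivity["I"].as_percent() == (100.0, 72.2, 100.0)
        assert s.stage_sensitivity["II"].successes == 17

    def test_empty_stratum_warns_and_omits_ci(self):
        labels = np.r_[np.ones(4, int), np.zeros(4, int)]
        stages = np.array(["II"] * 4 + ["none"] * 4)
        with pytest.warns(UserWarning, match="stage I"):
            s = confusion_summary(np.ones(8, bool), labels, stages)
        assert "I" not in s.stage_sensitivity
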