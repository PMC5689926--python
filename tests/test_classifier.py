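"""Overlap metric, threshold classifier, confusion counts, rank-sum test."""

import numpy as np
import pytest
from conftest import cohort_from_metrics
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hypotriage import (
    ThresholdModel,
    classify,
    compare_groups,
    evaluate,
    fit_threshold,
    overlap_metric,
    rank_sum_test,
)
from hypotriage.classifier import _candidate_thresholds, _confusion_arrays
from hypotriage.errors import DegenerateCohortError


class TestOverlapMetric:
    @pytest.mark.parametrize(
        "f_bw,f_rw,expected",
        [
            (0.0, 0.0, 0.0),
            (0.3, 0.4, 0.5),
            (0.164, 0.220, 0.2744),  # quadrature of the per-wall thresholds
        ],
    )
    def test_values(self, f_bw, f_rw, expected):
        assert overlap_metric(f_bw, f_rw) == pytest.approx(expected, abs=1e-4)

    @pytest.mark.parametrize("f_bw,f_rw", [(-0.1, 0.2), (0.2, 1.3)])
    def test_domain(self, f_bw, f_rw):
        with pytest.raises(ValueError):
            overlap_metric(f_bw, f_rw)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        f_bw=st.floats(0.0, 1.0),
        f_rw=st.floats(0.0, 1.0),
        bump=st.floats(1e-6, 0.5),
    )
    def test_monotone_and_dominates_components(self, f_bw, f_rw, bump):
        m = overlap_metric(f_bw, f_rw)
        assert m >= max(f_bw, f_rw)
        assert m <= np.sqrt(2.0) + 1e-12
        if f_bw + bump <= 1.0:
            assert overlap_metric(f_bw + bump, f_rw) > m


class TestClassify:
    def test_boundary_value_is_ineligible(self):
        model = ThresholdModel(0.278)
        assert classify(0.278, model) == "ineligible"
        assert classify(0.0, model) == "eligible"

    def test_between_the_reference_radii(self):
        assert classify(0.305, ThresholdModel(0.274)) == "ineligible"


class TestFitThreshold:
    def test_separated_cohort_midpoint(self):
        cohort = cohort_from_metrics([0.1, 0.2, 0.4, 0.5], [True, True, False, False])
        model = fit_threshold(cohort)
        assert model.threshold == pytest.approx(0.3)
        assert model.training_accuracy == 1.0

    def test_anti_separated_returns_smallest_optimum(self):
        cohort = cohort_from_metrics([0.1, 0.2], [False, True])
        model = fit_threshold(cohort)
        assert model.training_accuracy == 0.5
        # candidates achieving 0.5: the all-ineligible sentinel (smallest)
        # and the all-eligible sentinel; smallest wins.
        assert model.threshold == 0.0

    def test_perfect_separation_gives_accuracy_one(self):
        rng = np.random.default_rng(0)
        metrics = np.concatenate([rng.uniform(0, 0.2, 10), rng.uniform(0.3, 0.5, 6)])
        cohort = cohort_from_metrics(metrics, [True] * 10 + [False] * 6)
        assert fit_threshold(cohort).training_accuracy == 1.0

    def test_single_class_raises(self):
        with pytest.raises(DegenerateCohortError):
            fit_threshold(cohort_from_metrics([0.1, 0.2], [True, True]))

    def test_optimal_over_exhaustive_candidates(self):
        rng = np.random.default_rng(123)
        for _ in range(25):
            n = int(rng.integers(4, 30))
            metrics = rng.uniform(0, 0.6, n).round(3)
            labels = rng.random(n) < 0.6
            if labels.all() or not labels.any():
                continue
            cohort = cohort_from_metrics(metrics, labels)
            model = fit_threshold(cohort)
            # every candidate, including a dense sweep, does no better
            sweep = np.concatenate([_candidate_thresholds(metrics), np.linspace(0, 0.7, 141)])
            for t in sweep:
                acc = np.mean((metrics < t) == labels)
                assert acc <= model.training_accuracy + 1e-12


class TestEvaluate:
    def test_all_correct(self, separable_cohort):
        model = fit_threshold(separable_cohort)
        counts = evaluate(separable_cohort, model)
        assert counts.sensitivity == counts.specificity == counts.accuracy == 1.0

    def test_threshold_below_all_values_flags_everyone(self):
        cohort = cohort_from_metrics([0.1, 0.2, 0.3, 0.4], [True, True, False, False])
        counts = evaluate(cohort, ThresholdModel(0.0))
        assert (counts.tp, counts.fn, counts.tn, counts.fp) == (0, 2, 2, 0)
        assert counts.sensitivity == 0.0
        assert counts.specificity == 1.0
        assert counts.accuracy == 0.5

    def test_counts_partition_cohort(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n = int(rng.integers(2, 40))
            metrics = rng.uniform(0, 0.6, n)
            labels = rng.random(n) < 0.5
            counts = evaluate(
                cohort_from_metrics(metrics, labels), ThresholdModel(float(rng.uniform(0, 0.6)))
            )
            assert counts.total == n

    def test_accuracy_equals_mean_correctness(self):
        rng = np.random.default_rng(21)
        metrics = rng.uniform(0, 0.6, 25)
        labels = rng.random(25) < 0.6
        threshold = 0.28
        counts = evaluate(cohort_from_metrics(metrics, labels), ThresholdModel(threshold))
        per_patient = np.mean((metrics < threshold) == labels)
        assert counts.accuracy == pytest.approx(per_patient)

    def test_label_flip_maps_sensitivity_to_specificity(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(0, 1, 30)
        labels = rng.random(30) < 0.5
        threshold = 0.43
        tp, fp, tn, fn = _confusion_arrays(values, labels, threshold)
        # flip labels and the rule's polarity (predict ineligible iff v < t)
        flipped_pred_eligible = values >= threshold
        ftp = np.count_nonzero(flipped_pred_eligible & ~labels)
        ffn = np.count_nonzero(~flipped_pred_eligible & ~labels)
        ftn = np.count_nonzero(~flipped_pred_eligible & labels)
        ffp = np.count_nonzero(flipped_pred_eligible & labels)
        assert ftp / (ftp + ffn) == pytest.approx(tn / (tn + fp))  # sens' == spec
        assert ftn / (ftn + ffp) == pytest.approx(tp / (tp + fn))  # spec' == sens


class TestRankSum:
    def test_identical_groups(self):
        result = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert result.statistic == 0.0
        assert result.pvalue == pytest.approx(1.0)

    def test_fully_separated_small_groups_match_exact_enumeration(self):
        result = rank_sum_test([1, 2, 3], [10, 11, 12])
        # exact two-sided p for the minimal rank-sum with n=3,3 is 2/20 = 0.1
        assert result.statistic < 0
        assert result.pvalue == pytest.approx(0.1, abs=0.05)

    def test_symmetric_under_group_swap(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 9)
        r1, r2 = rank_sum_test(a, b), rank_sum_test(b, a)
        assert r1.pvalue == pytest.approx(r2.pvalue)
        assert r1.statistic == pytest.approx(-r2.statistic)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(7)
        a = np.round(rng.normal(0, 1, 20), 1)  # rounding induces ties
        b = np.round(rng.normal(0.7, 1, 25), 1)
        ours = rank_sum_test(a, b)
        reference = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert ours.pvalue == pytest.approx(reference.pvalue, rel=1e-6)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


def test_compare_groups_flags_informative_features(noisy_cohort):
    table = compare_groups(noisy_cohort).set_index("feature")
    # the metric drives the labels, so its separation is overwhelming
    assert table.loc["metric", "p_value"] < 1e-10
    assert table.loc["f_rw", "p_value"] < 1e-3
    assert table.loc["metric", "median_ineligible"] > table.loc["metric", "median_eligible"]
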