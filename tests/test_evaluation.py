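"""Evaluation statistics against brute-force and closed-form oracles."""

import numpy as np
import pytest
from scipy import stats

from minipae.evaluation import (
    ConfusionCounts,
    bootstrap_auc_ci,
    cohens_kappa,
    counts_from_predictions,
    evaluate,
    mcnemar_test,
    metrics_from_counts,
    roc_auc,
    round_half_away,
)


def pairwise_auc_oracle(labels, scores):
    """All-pairs probability P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestMetricsFromCounts:
    def test_perfect_classifier(self):
        m = metrics_from_counts(ConfusionCounts(tp=40, fp=0, tn=40, fn=0))
        assert m["sensitivity"] == m["specificity"] == m["f1"] == 1.0

    def test_balanced_worked_example(self):
        """40/40 classes with 5 FN and 7 FP."""
        m = metrics_from_counts(ConfusionCounts(tp=35, fn=5, fp=7, tn=33))
        assert round_half_away(m["f1"]) == 0.85
        assert round_half_away(m["sensitivity"]) == 0.88

    def test_imbalanced_worked_example(self):
        """42/83 classes with 9 FN and 19 FP."""
        m = metrics_from_counts(ConfusionCounts(tp=33, fn=9, fp=19, tn=64))
        assert round_half_away(m["sensitivity"]) == 0.79
        assert round_half_away(m["specificity"]) == 0.77
        assert round_half_away(m["f1"]) == 0.70

    def test_zero_predictions_give_zero_precision_f1(self):
        m = metrics_from_counts(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert m["precision"] == 0.0 and m["f1"] == 0.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_counts(ConfusionCounts(0, 0, 0, 0))

    def test_counts_from_predictions(self):
        c = counts_from_predictions([1, 1, 0, 0], [1, 0, 1, 0])
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 1)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([1, 0], [0.5, 0.5]) == 0.5

    def test_matches_all_pairs_oracle(self, rng):
        scores = rng.integers(0, 10, size=20) / 10.0  # force some ties
        labels = rng.integers(0, 2, size=20)
        labels[0], labels[1] = 0, 1
        assert roc_auc(labels, scores) == pytest.approx(
            pairwise_auc_oracle(labels, scores), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(30)
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1
        assert roc_auc(labels, scores) == pytest.approx(
            roc_auc(labels, np.exp(3 * scores)), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.1, 0.2])


class TestBootstrapCi:
    def test_seeded_reproducibility(self, rng):
        scores = rng.random(40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        a = bootstrap_auc_ci(labels, scores, n_iter=200, seed=7)
        b = bootstrap_auc_ci(labels, scores, n_iter=200, seed=7)
        assert a == b

    def test_perfect_separation_collapses_to_one(self):
        labels = [0] * 50 + [1] * 50
        scores = list(np.linspace(0, 0.4, 50)) + list(np.linspace(0.6, 1, 50))
        lo, hi = bootstrap_auc_ci(labels, scores, n_iter=200, seed=1)
        assert lo == pytest.approx(1.0, abs=1e-9)
        assert hi == pytest.approx(1.0, abs=1e-9)

    def test_interval_brackets_point_auc(self, rng):
        scores = rng.random(60)
        labels = (scores + rng.normal(0, 0.3, 60) > 0.5).astype(int)
        labels[:2] = [0, 1]
        auc = roc_auc(labels, scores)
        lo, hi = bootstrap_auc_ci(labels, scores, n_iter=500, seed=3)
        assert lo <= auc <= hi


class TestMcNemar:
    def test_no_discordant_pairs(self):
        stat, p = mcnemar_test([True, False, True], [True, False, True])
        assert p == 1.0

    def test_exact_binomial_enumeration(self):
        """b=5, c=1 -> two-sided p = 2 * P(Bin(6, 0.5) <= 1) = 0.21875."""
        a = [True] * 5 + [False] * 1 + [True] * 10
        b = [False] * 5 + [True] * 1 + [True] * 10
        _, p = mcnemar_test(a, b)
        enum = 2 * sum(stats.binom.pmf(k, 6, 0.5) for k in (0, 1))
        assert p == pytest.approx(enum, abs=1e-12)
        assert p == pytest.approx(0.21875, abs=1e-12)

    def test_chi_square_branch_with_continuity_correction(self):
        # 30 discordant pairs: chi2 = (|20-10|-1)^2 / 30
        a = [True] * 20 + [False] * 10 + [True] * 40
        b = [False] * 20 + [True] * 10 + [True] * 40
        stat, p = mcnemar_test(a, b)
        expected_stat = (abs(20 - 10) - 1) ** 2 / 30
        assert stat == pytest.approx(expected_stat, abs=1e-9)
        assert p == pytest.approx(stats.chi2.sf(expected_stat, 1), abs=1e-9)

    def test_symmetry(self):
        a = [True] * 5 + [False] * 2 + [True] * 5
        b = [False] * 5 + [True] * 2 + [True] * 5
        assert mcnemar_test(a, b)[1] == pytest.approx(mcnemar_test(b, a)[1], abs=1e-12)


class TestCohensKappa:
    def test_identical_nonconstant_raters(self):
        assert cohens_kappa([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0

    def test_hand_computed_two_by_two_table(self):
        """a=50, b=10, c=10, d=30: p_o = 0.8, p_e = 0.6*0.6 + 0.4*0.4 = 0.52,
        kappa = 0.28 / 0.48 = 0.58333."""
        ra = [1] * 50 + [1] * 10 + [0] * 10 + [0] * 30
        rb = [1] * 50 + [0] * 10 + [1] * 10 + [0] * 30
        k = cohens_kappa(ra, rb)
        assert k == pytest.approx((0.8 - 0.52) / (1 - 0.52), abs=1e-12)

    def test_independent_random_labels_near_zero(self, rng):
        a = rng.integers(0, 2, size=4000)
        b = rng.integers(0, 2, size=4000)
        assert abs(cohens_kappa(a, b)) < 0.06

    def test_both_raters_constant_rejected(self):
        with pytest.raises(ValueError):
            cohens_kappa([1, 1, 1], [1, 1, 1])


def test_evaluate_report_consistency(rng):
    scores = rng.random(50)
    labels = (scores > 0.5).astype(int)
    labels[:2] = [0, 1]
    rep = evaluate(labels, scores, threshold=0.5, n_bootstrap=100, seed=2)
    m = metrics_from_counts(rep.counts)
    assert rep.sensitivity == m["sensitivity"]
    assert rep.auc_ci[0] <= rep.auc <= rep.auc_ci[1]
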