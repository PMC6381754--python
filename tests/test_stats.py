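"""Unit and property tests for the shared statistical primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from methsig import stats
from conftest import brute_force_youden, exact_ranksum_p, pairwise_auc


class TestRankSum:
    @pytest.mark.parametrize(
        "a, b, expected_p",
        [
            ([1, 2], [3, 4], 1 / 3),  # most extreme split of C(4,2)=6, doubled
            ([0.1, 0.2, 0.15, 0.12], [0.5, 0.6, 0.55, 0.52], 2 / 70),
        ],
    )
    def test_exact_examples(self, a, b, expected_p):
        res = stats.rank_sum_test(a, b)
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(expected_p)
        assert res.p_two_sided == pytest.approx(exact_ranksum_p(a, b))

    def test_identical_groups_are_degenerate_symmetric(self):
        res = stats.rank_sum_test([0.3, 0.5, 0.7], [0.3, 0.5, 0.7])
        assert res.u_statistic == pytest.approx(9 / 2)
        assert res.p_two_sided == 1.0

    def test_constant_pooled_is_flagged(self):
        res = stats.rank_sum_test([1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.degenerate and res.p_two_sided == 1.0
        assert res.u_statistic == pytest.approx(3.0)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            stats.rank_sum_test([1.0], [2.0, 3.0])

    def test_exact_limit_switches_method(self):
        a, b = [1, 2, 3], [4, 5, 6]
        assert stats.rank_sum_test(a, b, exact_limit=6).method == "exact"
        assert stats.rank_sum_test(a, b, exact_limit=5).method == "normal_approx"

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.data())
    def test_exact_p_matches_enumeration_oracle(self, data):
        """Exact p equals full enumeration for untied combined n <= 10."""
        n_a = data.draw(st.integers(2, 5))
        n_b = data.draw(st.integers(2, min(5, 10 - n_a)))
        pool = data.draw(
            st.lists(st.integers(0, 1000), min_size=n_a + n_b,
                     max_size=n_a + n_b, unique=True)
        )
        a, b = pool[:n_a], pool[n_a:]
        res = stats.rank_sum_test(a, b, exact_limit=10)
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(exact_ranksum_p(a, b))


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 3.0, 5.0]
        rho_inv, _ = stats.spearman_correlation(x, [9, 7, 3, 1])
        rho_id, _ = stats.spearman_correlation(x, x)
        assert rho_inv == pytest.approx(-1.0)
        assert rho_id == pytest.approx(1.0)

    def test_hand_computed_rank_example(self):
        # d = (1,1,1,1) pairwise -> rho = 1 - 6*4/(64-4) = 0.6
        rho, p = stats.spearman_correlation([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)
        assert 0.0 <= p <= 1.0

    def test_constant_margin_raises(self):
        with pytest.raises(ValueError):
            stats.spearman_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRoc:
    def test_perfect_separation(self):
        roc = stats.roc_with_bootstrap([3, 4, 1, 2], [1, 1, 0, 0], n_boot=50, seed=0)
        assert roc.auc == 1.0
        assert roc.youden_j == pytest.approx(1.0)

    def test_identical_distributions_half(self):
        roc = stats.roc_with_bootstrap([1, 2, 1, 2], [1, 1, 0, 0], n_boot=50, seed=0)
        assert roc.auc == pytest.approx(0.5)

    def test_ties_half_counted(self):
        # pairs: 4>3, 4>1, 3=3, 3>1, 2<3, 2>1 -> (4 + 0.5)/6
        roc = stats.roc_with_bootstrap([4, 3, 2, 3, 1], [1, 1, 1, 0, 0],
                                       n_boot=50, seed=0)
        assert roc.auc == pytest.approx(4.5 / 6)
        assert roc.auc == pytest.approx(pairwise_auc([4, 3, 2], [3, 1]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            stats.roc_with_bootstrap([1, 2], [1, 1], n_boot=10, seed=0)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.data())
    def test_auc_equals_rank_sum_u(self, data):
        """AUC = U/(n_pos*n_neg) with the U of the rank test on classes."""
        pos = data.draw(st.lists(st.integers(0, 20), min_size=2, max_size=8))
        neg = data.draw(st.lists(st.integers(0, 20), min_size=2, max_size=8))
        scores = np.array(pos + neg, float)
        labels = np.array([1] * len(pos) + [0] * len(neg), bool)
        auc = stats.auc_from_scores(scores, labels)
        u = stats.rank_sum_test(pos, neg).u_statistic
        assert auc == pytest.approx(u / (len(pos) * len(neg)))
        assert auc == pytest.approx(pairwise_auc(pos, neg))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.data())
    def test_youden_matches_brute_force_scan(self, data):
        scores = data.draw(st.lists(st.integers(-5, 5), min_size=4, max_size=12))
        n_pos = data.draw(st.integers(1, len(scores) - 1))
        labels = [1] * n_pos + [0] * (len(scores) - n_pos)
        roc = stats.roc_with_bootstrap(scores, labels, n_boot=1, seed=0)
        j, cutoff = brute_force_youden(scores, labels)
        assert roc.youden_j == pytest.approx(j)
        assert roc.youden_cutoff == cutoff

    def test_bootstrap_reproducible_and_point_auc_stable(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.4
        labels[0], labels[1] = True, False
        r1 = stats.roc_with_bootstrap(scores, labels, n_boot=100, seed=42)
        r2 = stats.roc_with_bootstrap(scores, labels, n_boot=100, seed=42)
        r3 = stats.roc_with_bootstrap(scores, labels, n_boot=1000, seed=42)
        assert (r1.auc_ci_low, r1.auc_ci_high) == (r2.auc_ci_low, r2.auc_ci_high)
        assert r1.auc == r3.auc  # point estimate independent of n_boot
        assert r1.auc_ci_low <= r1.auc <= r1.auc_ci_high

    def test_roc_curve_against_sklearn(self):
        """Independent cross-check of the empirical curve and AUC."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        scores = rng.normal(size=50) + np.repeat([1.0, 0.0], 25)
        labels = np.repeat([True, False], 25)
        auc = stats.auc_from_scores(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores))


class TestLogistic:
    def test_intercept_only_closed_form(self):
        fit = stats.logistic_fit(np.empty((4, 0)), [0, 0, 1, 1])
        assert fit.log_likelihood == pytest.approx(4 * math.log(0.5))
        assert fit.aic == pytest.approx(2 - 8 * math.log(0.5))
        assert fit.n_params == 1 and fit.converged

    def test_all_one_labels_degenerate(self):
        fit = stats.logistic_fit(np.empty((3, 0)), [1, 1, 1])
        assert not fit.converged
        assert fit.log_likelihood == 0.0
        assert math.isinf(fit.intercept)

    def test_perfect_separation_flagged_with_aic(self):
        fit = stats.logistic_fit(np.array([[1.0], [2.0], [5.0], [6.0]]), [0, 0, 1, 1])
        assert not fit.converged
        assert math.isfinite(fit.aic)
        assert fit.coefficients[0] > 0  # likelihood ascends along the separator

    def test_constant_feature_dropped(self):
        X = np.column_stack([np.ones(6), [1, 2, 3, 1, 2, 4]])
        with pytest.warns(UserWarning, match="constant"):
            fit = stats.logistic_fit(X, [0, 0, 1, 0, 1, 1], feature_names=("c", "x"))
        assert fit.dropped_features == ("c",)
        assert fit.feature_names == ("x",)

    def test_aic_definition_holds(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 2))
        y = (X[:, 0] + rng.normal(size=40) > 0).astype(float)
        fit = stats.logistic_fit(X, y)
        assert fit.converged
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.log_likelihood)
        # cross-check the MLE against an unpenalised sklearn fit
        from sklearn.linear_model import LogisticRegression

        sk = LogisticRegression(C=1e10, max_iter=500).fit(X, y)
        assert fit.coefficients == pytest.approx(sk.coef_[0], abs=1e-3)


class TestSampleSize:
    def test_study_design_values(self):
        plan = stats.two_proportion_sample_size(0.45, 0.10, 0.05, 0.80, dropout=0.15)
        assert plan.n_per_group == 22
        assert plan.n_total == 44
        assert plan.n_with_dropout == 51

    def test_formula_evaluation(self):
        # ceil[(1.959964+0.841621)^2 * 0.48 / 0.04] = ceil(94.19)
        assert stats.two_proportion_sample_size(0.60, 0.40).n_per_group == 95

    def test_equal_proportions_rejected(self):
        with pytest.raises(ValueError):
            stats.two_proportion_sample_size(0.3, 0.3)

    @pytest.mark.parametrize("n_total, dropout, expected",
                             [(44, 0.15, 51), (10, 0.0, 10), (100, 0.15, 115)])
    def test_dropout_inflation(self, n_total, dropout, expected):
        assert stats.inflate_for_dropout(n_total, dropout) == expected

    def test_dropout_out_of_range(self):
        with pytest.raises(ValueError):
            stats.inflate_for_dropout(10, 1.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        p2=st.floats(0.05, 0.4),
        gap1=st.floats(0.1, 0.3),
        gap2=st.floats(0.05, 0.09),
        power=st.floats(0.7, 0.95),
    )
    def test_monotonicity(self, p2, gap1, gap2, power):
        """Larger effects need fewer patients; more power needs more."""
        wide = stats.two_proportion_sample_size(p2 + gap1 + gap2, p2, power=power)
        narrow = stats.two_proportion_sample_size(p2 + gap1, p2, power=power)
        assert wide.n_per_group <= narrow.n_per_group
        more_power = stats.two_proportion_sample_size(p2 + gap1, p2, power=min(power + 0.04, 0.99))
        assert more_power.n_per_group >= narrow.n_per_group
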