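import itertools
import math
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from digitalmarker import (
    ExpressionMatrix,
    ValidationError,
    count_stable_genes,
    filter_by_correlation,
    filter_by_expression,
    score_fisher_ld,
    score_mannwhitney,
    synthesize_scores,
)
from digitalmarker.datamodel import EFFECTIVE, INEFFECTIVE, DrugResponse
from digitalmarker.screening import extreme_groups, fisher_ld

from conftest import make_continuous_response


def expr(rows, genes=None, samples=None, **kw):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    samples = samples or [f"s{j}" for j in range(rows.shape[1])]
    return ExpressionMatrix(pd.DataFrame(rows, index=genes, columns=samples),
                            **kw)


class TestExpressionFilter:
    def test_high_expression_retained(self):
        # mean log10(1+99) = 2 > 1
        assert filter_by_expression(expr([[99, 99, 99]]), 1.0, 1) == ["g0"]

    def test_boundary_is_strict(self):
        # mean log10(1+9) = 1 exactly: strict > rejects
        assert filter_by_expression(expr([[9, 9, 9]]), 1.0, 1) == []

    def test_zero_tpm_fails_patient_filter(self):
        assert filter_by_expression(expr([[0, 100]]), 0.0, 0) == []

    def test_patient_filter_geometric_mean(self):
        # mean log10 of {10, 10} = 1 > 0
        assert filter_by_expression(expr([[10, 10]]), 0.0, 0) == ["g0"]

    def test_invalid_pseudo(self):
        with pytest.raises(ValidationError):
            filter_by_expression(expr([[1]]), 0.0, 2)

    @given(st.lists(st.floats(min_value=0, max_value=1e4, allow_nan=False),
                    min_size=3, max_size=8),
           st.floats(min_value=-1, max_value=3),
           st.floats(min_value=0, max_value=1.5))
    def test_raising_threshold_shrinks_gene_set(self, tpm, thr, delta):
        x = expr([tpm])
        low = set(filter_by_expression(x, thr, 1))
        high = set(filter_by_expression(x, thr + delta, 1))
        assert high <= low


class TestCorrelationFilter:
    def test_perfect_positive_retained(self):
        x = expr([[1, 2, 3, 4]])
        r = make_continuous_response(x.samples, [1, 2, 3, 4])
        assert filter_by_correlation(x, r, 0.25) == ["g0"]

    def test_negative_correlation_sign_policy(self):
        x = expr([[1, 2, 3, 4]])
        r = make_continuous_response(x.samples, [-1, -2, -3, -4])
        assert filter_by_correlation(x, r, 0.25, use_abs=True) == ["g0"]
        assert filter_by_correlation(x, r, 0.25, use_abs=False) == []

    def test_constant_gene_dropped(self):
        x = expr([[5, 5, 5, 5]])
        r = make_continuous_response(x.samples, [1, 2, 3, 4])
        assert filter_by_correlation(x, r, 0.25) == []

    def test_too_few_overlapping_samples(self):
        x = expr([[1, 2]])
        r = make_continuous_response(x.samples, [1, 2])
        with pytest.raises(ValidationError, match="overlapping"):
            filter_by_correlation(x, r, 0.25)

    def test_matches_scipy_pearson(self, rng):
        x = expr(rng.uniform(0, 100, size=(20, 12)))
        z = rng.standard_normal(12)
        r = make_continuous_response(x.samples, z)
        kept = set(filter_by_correlation(x, r, 0.3, use_abs=True))
        for i, g in enumerate(x.genes):
            rho = stats.pearsonr(x.values.iloc[i], z).statistic
            assert (abs(rho) > 0.3) == (g in kept)

    def test_permutation_null_pass_rate(self, rng):
        """Under label permutation the pass fraction matches the null tail."""
        n_genes, n = 2000, 40
        x = expr(10.0 ** rng.normal(1.5, 0.5, size=(n_genes, n)))
        z = rng.standard_normal(n)
        r = make_continuous_response(x.samples, z)
        frac = len(filter_by_correlation(x, r, 0.25)) / n_genes
        # analytic two-sided tail of the null correlation distribution
        t = 0.25 * math.sqrt((n - 2) / (1 - 0.25 ** 2))
        p0 = 2 * stats.t.sf(t, df=n - 2)
        tol = 5 * math.sqrt(p0 * (1 - p0) / n_genes) + 0.02
        assert abs(frac - p0) < tol


def fisher_oracle(low, high):
    """Direct-formula oracle using the statistics module."""
    mu = statistics.fmean(high) - statistics.fmean(low)
    var = statistics.variance(high) + statistics.variance(low)
    if var == 0:
        return 0.0 if mu == 0 else math.inf
    return abs(mu) / math.sqrt(var)


class TestFisherLD:
    def test_hand_computed_example(self):
        # unbiased variances of {1,2,3} and {7,8,9} are both 1
        score = fisher_ld(np.array([[1.0, 2, 3]]), np.array([[7.0, 8, 9]]))
        assert score[0] == pytest.approx(6 / math.sqrt(2), abs=1e-12)

    def test_identical_groups_score_zero(self):
        assert fisher_ld(np.array([[5.0, 5]]), np.array([[5.0, 5]]))[0] == 0.0

    def test_zero_variance_unequal_means_is_infinite(self):
        assert fisher_ld(np.array([[1.0, 1]]), np.array([[2.0, 2]]))[0] \
            == np.inf

    def test_small_cohort_rejected(self):
        x = expr([[1, 2, 3]])
        r = make_continuous_response(x.samples, [1, 2, 3])
        with pytest.raises(ValidationError, match=">= 4"):
            score_fisher_ld(x, r)

    def test_extreme_groups_tail_sizes_and_tie_order(self):
        r = make_continuous_response(
            ["s3", "s1", "s2", "s4", "s5", "s6"], [0.0, 0.0, -1, -2, 1, 2])
        low, high = extreme_groups(r, 0.15)  # floor(0.9) -> min 2 per tail
        assert low == ["s4", "s2"]
        assert high == ["s5", "s6"]
        # the two z = 0 ties order by sample identifier
        low3, _ = extreme_groups(r, 0.5)
        assert low3 == ["s4", "s2", "s1"]

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(1000):
            n_low = rng.integers(2, 7)
            n_high = rng.integers(2, 7)
            low = rng.normal(size=(1, n_low))
            high = rng.normal(size=(1, n_high))
            expected = fisher_oracle(low[0].tolist(), high[0].tolist())
            assert fisher_ld(low, high)[0] == pytest.approx(expected,
                                                            rel=1e-10)

    def test_uses_log_scale_and_extreme_tails(self, rng):
        n = 20
        z = rng.standard_normal(n)
        x = expr(rng.uniform(0, 50, size=(5, n)))
        r = make_continuous_response(x.samples, z)
        scores = score_fisher_ld(x, r, 0.15)
        low, high = extreme_groups(r, 0.15)
        logv = np.log10(1 + x.values)
        for g in x.genes:
            expected = fisher_oracle(logv.loc[g, low].tolist(),
                                     logv.loc[g, high].tolist())
            assert scores[g] == pytest.approx(expected, rel=1e-10)


def mw_exact_oracle(g1, g2):
    """Two-sided exact Mann-Whitney p by enumerating all rank splits.

    Counts the splits whose smaller U statistic is at least as extreme
    as observed; both tails are covered by the min, so no doubling.
    """
    pooled = list(g1) + list(g2)
    n1, n2 = len(g1), len(g2)
    ranks = stats.rankdata(pooled)
    u1_obs = sum(ranks[:n1]) - n1 * (n1 + 1) / 2
    u_obs = min(u1_obs, n1 * n2 - u1_obs)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        u1 = sum(ranks[i] for i in comb) - n1 * (n1 + 1) / 2
        count += min(u1, n1 * n2 - u1) <= u_obs
        total += 1
    return min(1.0, count / total)


def binary_response(samples, labels):
    arr = np.array([EFFECTIVE if l else INEFFECTIVE for l in labels],
                   dtype=object)
    return DrugResponse("d", list(samples), "binary", label=arr)


class TestMannWhitney:
    def test_enumerated_small_example(self):
        # {1,2} vs {3,4}: 1 of C(4,2)=6 splits is as extreme, two-sided
        x = expr([[1, 2, 3, 4]])
        r = binary_response(x.samples, [1, 1, 0, 0])
        score = score_mannwhitney(x, r)["g0"]
        assert score == pytest.approx(-math.log10(2 / 6), abs=1e-12)

    def test_identical_tied_groups_score_zero(self):
        x = expr([[1, 2, 1, 2]])
        r = binary_response(x.samples, [1, 1, 0, 0])
        assert score_mannwhitney(x, r)["g0"] == 0.0

    def test_perfect_separation_exact_p(self):
        x = expr([list(range(1, 17))])
        r = binary_response(x.samples, [1] * 8 + [0] * 8)
        expected = -math.log10(2 / math.comb(16, 8))
        assert score_mannwhitney(x, r)["g0"] == pytest.approx(expected,
                                                              abs=1e-9)

    def test_empty_class_rejected(self):
        x = expr([[1, 2, 3]])
        r = binary_response(x.samples, [1, 1, 1])
        with pytest.raises(ValidationError):
            score_mannwhitney(x, r)

    def test_exact_branch_agrees_with_enumeration_oracle(self, rng):
        for _ in range(1000):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 6))
            g1 = rng.normal(size=n1)
            g2 = rng.normal(size=n2)
            x = expr([np.concatenate([g1, g2]) + 10.0])
            r = binary_response(x.samples, [1] * n1 + [0] * n2)
            score = score_mannwhitney(x, r)["g0"]
            expected = mw_exact_oracle(list(g1 + 10.0), list(g2 + 10.0))
            assert 10.0 ** (-score) == pytest.approx(expected, rel=1e-9)

    def test_large_groups_use_tie_corrected_normal_approximation(self, rng):
        g1 = rng.integers(0, 6, size=12).astype(float)
        g2 = rng.integers(0, 6, size=15).astype(float)
        x = expr([np.concatenate([g1, g2])])
        r = binary_response(x.samples, [1] * 12 + [0] * 15)
        score = score_mannwhitney(x, r)["g0"]
        ref = stats.mannwhitneyu(g1, g2, alternative="two-sided",
                                 method="asymptotic").pvalue
        assert score == pytest.approx(-math.log10(ref), abs=1e-12)


class TestSynthesizeScores:
    def test_sum_and_rank(self):
        a = pd.Series({"g1": 2.0, "g2": 1.0})
        b = pd.Series({"g1": 0.5, "g2": 3.0})
        t = synthesize_scores(a, b)
        assert t.loc["g2", "score_combined"] == 4.0
        assert t.loc["g2", "rank"] == 1
        assert t.loc["g1", "rank"] == 2

    def test_empty_intersection_is_hard_error(self):
        with pytest.raises(ValidationError, match="relax"):
            synthesize_scores(pd.Series({"g1": 1.0}), pd.Series({"g2": 1.0}))

    def test_ties_break_lexicographically(self):
        a = pd.Series({"g2": 1.0, "g1": 1.0})
        b = pd.Series({"g2": 1.0, "g1": 1.0})
        t = synthesize_scores(a, b)
        assert list(t.index) == ["g1", "g2"]
        assert list(t["rank"]) == [1, 2]

    def test_rank_percentile_mode(self):
        a = pd.Series({"g1": 100.0, "g2": 1.0, "g3": 50.0})
        b = pd.Series({"g1": 0.1, "g2": 0.3, "g3": 0.2})
        t = synthesize_scores(a, b, mode="rank_percentile_sum")
        # g1: 3/3 + 1/3; g2: 1/3 + 3/3; g3: 2/3 + 2/3 -> three-way tie
        assert t["score_combined"].nunique() == 1
        assert list(t.index) == ["g1", "g2", "g3"]

    @given(st.dictionaries(st.sampled_from([f"g{i}" for i in range(8)]),
                           st.floats(0, 10, allow_nan=False),
                           min_size=1),
           st.dictionaries(st.sampled_from([f"g{i}" for i in range(8)]),
                           st.floats(0, 10, allow_nan=False),
                           min_size=1))
    def test_sum_mode_symmetric(self, da, db):
        shared = set(da) & set(db)
        if not shared:
            return
        a, b = pd.Series(da), pd.Series(db)
        t1 = synthesize_scores(a, b)
        t2 = synthesize_scores(b, a)
        pd.testing.assert_series_equal(t1["score_combined"],
                                       t2["score_combined"])
        pd.testing.assert_series_equal(t1["rank"], t2["rank"])


class TestStableGenes:
    def make_lists(self, count_a, count_b, n_drugs=30):
        la = {f"d{i}": (["g"] if i < count_a else []) + ["x"]
              for i in range(n_drugs)}
        lb = {f"d{i}": (["g"] if i < count_b else []) + ["y"]
              for i in range(n_drugs)}
        return la, lb

    def test_above_threshold_in_both_included(self):
        la, lb = self.make_lists(21, 21)
        t = count_stable_genes(la, lb, 20)
        assert t.loc["g", "count_a"] == 21
        assert t.loc["g", "count_b"] == 21

    def test_threshold_is_strict(self):
        la, lb = self.make_lists(25, 20)
        assert "g" not in count_stable_genes(la, lb, 20).index

    def test_single_dataset_gene_excluded(self):
        la, _ = self.make_lists(30, 0)
        t = count_stable_genes(la, {"d0": ["z"] * 1}, 20)
        assert "g" not in t.index and "x" not in t.index
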