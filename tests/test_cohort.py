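"""Eligibility filter and between-region comparison statistics.

Oracles: direct Sum (O-E)^2/E evaluation for the chi-square, exhaustive
enumeration of same-margin tables for Fisher's exact test, and a from-scratch
implementation of the pooled/Welch formulas for the t statistic.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import comb
from scipy.stats import t as t_dist

from careshed import (
    SummaryStatPair,
    ValidationError,
    association_test,
    compare_report,
    expected_counts,
    filter_eligible,
    fisher_exact_2x2,
    format_report_text,
    pearson_chi2,
    two_sample_t,
)


def chi2_oracle(table):
    t = np.asarray(table, dtype=float)
    e = np.outer(t.sum(1), t.sum(0)) / t.sum()
    return float(((t - e) ** 2 / e).sum())


def fisher_oracle(table):
    """Two-sided Fisher p by full enumeration over same-margin tables."""
    (a, b), (c, d) = np.asarray(table, dtype=int)
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(a_):
        return (comb(r1, a_, exact=True) * comb(r2, c1 - a_, exact=True)
                / comb(n, c1, exact=True))

    p_obs = prob(a)
    total = 0.0
    for a_ in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(a_)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


class TestFilterEligible:
    def test_threshold_is_inclusive(self):
        df = pd.DataFrame({"self_care_score": [39.92, 39.93, 100.0]})
        kept = filter_eligible(df)
        assert list(kept["self_care_score"]) == [39.93, 100.0]

    def test_empty_input(self):
        df = pd.DataFrame({"self_care_score": []})
        assert len(filter_eligible(df)) == 0

    def test_zero_threshold_is_identity(self):
        df = pd.DataFrame({"self_care_score": [0.0, 50.0, 100.0]})
        assert len(filter_eligible(df, threshold=0.0)) == 3

    def test_out_of_range_score_rejected(self):
        df = pd.DataFrame({"self_care_score": [101.0]})
        with pytest.raises(ValidationError):
            filter_eligible(df)


class TestPearsonChi2:
    # printed r x 2 counts from the motivating cohort and their statistics
    PRINTED = {
        "gender": ([[2618, 497], [3009, 459]], 9.78),
        "mental": ([[2470, 325], [3157, 631]], 32.78),
        "sensory": ([[653, 95], [4974, 861]], 2.26),
        "digestive": ([[234, 30], [5393, 926]], 2.21),
        "genitourinary": ([[384, 82], [5243, 874]], 3.82),
        "neuromusculoskeletal": ([[2587, 547], [3040, 409]], 41.41),
        "severity": ([[1206, 193], [1888, 288], [1031, 203], [1502, 272]], 8.133),
    }

    @pytest.mark.parametrize("name", sorted(PRINTED))
    def test_reproduces_printed_statistics(self, name):
        table, printed = self.PRINTED[name]
        ndp = 3 if name == "severity" else 2
        assert round(pearson_chi2(table).statistic, ndp) == printed

    def test_identical_column_proportions_give_zero(self):
        assert pearson_chi2([[10, 20], [5, 10]]).statistic == pytest.approx(0.0)

    def test_matches_direct_formula_oracle(self, rng):
        for _ in range(200):
            t = rng.integers(1, 60, (3, 2))
            assert pearson_chi2(t).statistic == pytest.approx(chi2_oracle(t))

    def test_df_and_p_range(self):
        res = pearson_chi2([[10, 20], [30, 5], [7, 7]])
        assert res.df == 2
        assert 0.0 <= res.p_value <= 1.0

    def test_invariant_under_row_and_column_permutation(self, rng):
        t = rng.integers(1, 50, (4, 2))
        base = pearson_chi2(t).statistic
        perm = t[rng.permutation(4)][:, ::-1]
        assert pearson_chi2(perm).statistic == pytest.approx(base)

    def test_2x2_equals_two_proportion_z_squared(self, rng):
        t = rng.integers(5, 80, (2, 2)).astype(float)
        (a, b), (c, d) = t
        n1, n2 = a + b, c + d
        p1, p2, p = a / n1, c / n2, (a + c) / (n1 + n2)
        z = (p1 - p2) / math.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
        assert pearson_chi2(t).statistic == pytest.approx(z**2)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValidationError):
            pearson_chi2([[0, 0], [3, 4]])


class TestFisherExact:
    def test_matches_enumeration_oracle_example(self):
        t = [[1, 9], [11, 3]]
        assert fisher_exact_2x2(t).p_value == pytest.approx(fisher_oracle(t))

    def test_balanced_table_p_is_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    @given(st.lists(st.integers(0, 10), min_size=4, max_size=4))
    def test_matches_enumeration_for_all_small_tables(self, cells):
        t = [[cells[0], cells[1]], [cells[2], cells[3]]]
        if np.any(np.sum(t, 0) == 0) or np.any(np.sum(t, 1) == 0):
            return
        assert fisher_exact_2x2(t).p_value == pytest.approx(fisher_oracle(t))

    def test_invariant_to_swapping_rows_and_columns(self, rng):
        t = rng.integers(0, 15, (2, 2)) + [[1, 0], [0, 1]]
        p1 = fisher_exact_2x2(t).p_value
        p2 = fisher_exact_2x2(t[::-1, ::-1]).p_value
        assert 0.0 <= p1 <= 1.0
        assert p1 == pytest.approx(p2)

    def test_non_2x2_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2([[1, 2], [3, 4], [5, 6]])

    def test_auto_switch_on_small_expected_cells(self):
        small = [[1, 9], [2, 3]]  # min expected cell < 5
        assert association_test(small).method == "fisher-exact"
        large = [[100, 120], [90, 110]]
        assert association_test(large).method == "pearson-chi2"


class TestTwoSampleT:
    AGE = SummaryStatPair(75.61, 12.0, 5627, 72.88, 11.7, 956)

    def test_reproduces_printed_age_statistic_pooled(self):
        res = two_sample_t(self.AGE, variant="pooled")
        assert round(res.statistic, 2) == 6.53
        assert res.df == 5627 + 956 - 2

    def test_identical_summaries_give_zero(self):
        pair = SummaryStatPair(10.0, 2.0, 30, 10.0, 2.0, 30)
        assert two_sample_t(pair).statistic == pytest.approx(0.0)

    @pytest.mark.parametrize("variant", ["pooled", "welch"])
    def test_matches_formula_oracle(self, rng, variant):
        for _ in range(50):
            m1, m2 = rng.normal(0, 5, 2)
            s1, s2 = rng.uniform(0.5, 4.0, 2)
            n1, n2 = rng.integers(3, 200, 2)
            pair = SummaryStatPair(m1, s1, int(n1), m2, s2, int(n2))
            res = two_sample_t(pair, variant=variant)
            if variant == "pooled":
                sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
                t_exp = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
                df_exp = n1 + n2 - 2
            else:
                va, vb = s1**2 / n1, s2**2 / n2
                t_exp = (m1 - m2) / math.sqrt(va + vb)
                df_exp = (va + vb) ** 2 / (va**2 / (n1 - 1) + vb**2 / (n2 - 1))
            assert res.statistic == pytest.approx(t_exp)
            assert res.df == pytest.approx(df_exp)
            p_exp = 2 * t_dist.sf(abs(t_exp), df_exp)
            assert res.p_value == pytest.approx(p_exp, rel=1e-6)

    def test_degenerate_variance_handling(self):
        equal = SummaryStatPair(5.0, 0.0, 10, 5.0, 0.0, 10)
        assert two_sample_t(equal).statistic == 0.0
        unequal = SummaryStatPair(5.0, 0.0, 10, 6.0, 0.0, 10)
        with pytest.raises(ValidationError):
            two_sample_t(unequal)


class TestReports:
    def test_compare_report_labels_variant_and_stars(self):
        rep = compare_report(
            contingency={"gender": [[2618, 497], [3009, 459]]},
            summaries={"age": TestTwoSampleT.AGE},
            t_variant="pooled",
        )
        assert rep["categorical"]["gender"]["stars"] == "**"
        assert rep["continuous"]["age"]["method"] == "t-pooled"
        assert rep["continuous"]["age"]["stars"] == "***"
        text = format_report_text(rep)
        assert "gender" in text and "age" in text

    def test_expected_counts_row_col_products(self):
        e = expected_counts([[10, 20], [30, 40]])
        np.testing.assert_allclose(e.sum(0), [40, 60])
        np.testing.assert_allclose(e.sum(1), [30, 70])
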