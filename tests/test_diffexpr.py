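"""Normalization, the exact count test and reporting arithmetic."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import nbinom

from oracles import mp_two_sided, rational_lower_tail, rational_pmf
from duomir.diffexpr import (
    ac_probability,
    ac_pvalue,
    apply_zero_rule,
    build_expression_table,
    categorize,
    expression_floor,
    fold_change,
    label_significance,
    normalize,
    percent,
    top_n,
)

# clean-read totals of the two goat ovary libraries (pregnant, non-pregnant)
N_PREG = 9_230_000
N_NONPREG = 11_010_000


class TestNormalize:
    def test_one_read_per_million(self):
        assert normalize(1, 10**6) == 1.0

    def test_mir21_normalized_expression(self):
        assert normalize(138_637, N_PREG) == pytest.approx(15020.3, abs=0.1)

    def test_zero_count(self):
        assert normalize(0, 10**6) == 0.0

    def test_invalid_total(self):
        with pytest.raises(ValueError):
            normalize(1, 0)


class TestZeroRuleAndFloor:
    @pytest.mark.parametrize(
        "ne,expected",
        [((0.0, 12.5), (0.01, 12.5)), ((3.2, 4.1), (3.2, 4.1)), ((0.0, 0.0), (0.01, 0.01))],
    )
    def test_zero_substitution(self, ne, expected):
        assert apply_zero_rule(*ne) == expected

    @pytest.mark.parametrize(
        "ne,included",
        [((0.01, 250.0), True), ((0.4, 0.7), False), ((1.0, 0.01), True)],
    )
    def test_floor_keeps_library_specific_mirnas(self, ne, included):
        assert expression_floor(*ne) is included


class TestFoldChange:
    def test_equal_expression(self):
        assert fold_change(10, 10) == 0.0

    def test_mir21_fold_change(self):
        fc = fold_change(normalize(138_637, N_PREG), normalize(43_703, N_NONPREG))
        assert fc == pytest.approx(1.92, abs=0.01)

    def test_let7a_fold_change(self):
        fc = fold_change(normalize(247_959, N_PREG), normalize(2_356_002, N_NONPREG))
        assert fc == pytest.approx(-2.99, abs=0.02)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fold_change(0.0, 1.0)

    @settings(max_examples=100, deadline=None)
    @given(
        a=st.floats(1e-3, 1e6, allow_nan=False),
        b=st.floats(1e-3, 1e6, allow_nan=False),
    )
    def test_antisymmetry(self, a, b):
        assert fold_change(a, b) == pytest.approx(-fold_change(b, a), abs=1e-9)


class TestExactProbability:
    def test_reduces_to_half_at_origin_with_equal_depth(self):
        assert ac_probability(0, 0, 10**6, 10**6) == pytest.approx(0.5, abs=1e-12)

    def test_equal_depth_closed_form(self):
        # with N1=N2 the law is Bin(x+y, 1/2) weighted by an extra 1/2
        assert ac_probability(5, 5, 100, 100) == pytest.approx(
            math.comb(10, 5) * 2**-11, rel=1e-12
        )

    def test_unequal_depth_against_rational_arithmetic(self):
        got = ac_probability(20, 5, 2 * 10**6, 10**6)
        assert got == pytest.approx(float(rational_pmf(20, 5, 2 * 10**6, 10**6)),
                                    rel=1e-12)

    def test_matches_negative_binomial_pmf(self):
        # independent route: p(y|x) is nbinom(y; x+1, N1/(N1+N2))
        for x, y, n1, n2 in [(3, 7, 500, 750), (0, 4, 100, 100), (50, 20, 9230, 11010)]:
            assert ac_probability(y, x, n1, n2) == pytest.approx(
                nbinom.pmf(y, x + 1, n1 / (n1 + n2)), rel=1e-10
            )

    @pytest.mark.parametrize("x", [0, 3, 17])
    @pytest.mark.parametrize("ratio", [(1, 1), (2, 1), (9230, 11010)])
    def test_distribution_sums_to_one(self, x, ratio):
        n1, n2 = (r * 1000 for r in ratio)
        total = sum(ac_probability(y, x, n1, n2) for y in range(3000))
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_no_overflow_at_sequencing_scale_counts(self):
        p = ac_probability(2_000_000, 2_000_100, 9_230_000, 11_010_000)
        assert 0 <= p < 1


class TestExactPvalue:
    def test_lower_tail_single_term(self):
        assert ac_pvalue(0, 0, 10, 10, "lower") == pytest.approx(0.5, rel=1e-12)

    def test_lower_tail_exact_rational_sum(self):
        # sum_{k<=5} C(5+k,k) 2^-(6+k)
        expected = sum(Fraction(math.comb(5 + k, k), 2 ** (6 + k)) for k in range(6))
        assert ac_pvalue(5, 5, 100, 100, "lower") == pytest.approx(
            float(expected), rel=1e-12
        )

    def test_tail_complement_identity(self):
        # C(y|x) + D(y+1|x) = 1, exact in rational arithmetic
        for x, y, n1, n2 in [(4, 6, 30, 20), (0, 3, 10, 10), (7, 0, 50, 90)]:
            lower = ac_pvalue(x, y, n1, n2, "lower")
            upper = ac_pvalue(x, y + 1, n1, n2, "upper")
            assert lower + upper == pytest.approx(1.0, rel=1e-12)
            assert lower == pytest.approx(
                float(rational_lower_tail(x, y, n1, n2)), rel=1e-12
            )

    def test_lower_tail_monotone_in_observed_count(self):
        ps = [ac_pvalue(10, y, 1000, 1000, "lower") for y in range(40)]
        assert all(a <= b for a, b in zip(ps, ps[1:]))

    def test_two_sided_matches_high_precision_oracle(self):
        got = ac_pvalue(100, 200, 10**6, 10**6)
        assert got == pytest.approx(float(mp_two_sided(100, 200, 10**6, 10**6)),
                                    rel=1e-10)

    def test_two_sided_capped_at_one(self):
        assert ac_pvalue(5, 5, 100, 100) <= 1.0

    def test_unknown_sidedness_rejected(self):
        with pytest.raises(ValueError):
            ac_pvalue(1, 1, 10, 10, sided="midp")


class TestLabels:
    @pytest.mark.parametrize(
        "fc,p,label",
        [
            (1.92, 0.001, "**"),
            (0.5, 1e-9, "none"),
            (-1.5, 0.03, "*"),
            (-1.5, 0.01, "*"),  # boundary: 0.01 <= p < 0.05
            (1.0, 0.001, "none"),  # boundary: |fc| must exceed 1
            (2.0, 0.05, "none"),
        ],
    )
    def test_label_rule(self, fc, p, label):
        assert label_significance(fc, p) == label


class TestPercent:
    @pytest.mark.parametrize(
        "part,whole,expected",
        [(471, 617, 76.34), (407, 617, 65.96), (90, 617, 14.59),
         (56, 617, 9.08), (0, 617, 0.0)],
    )
    def test_reporting_percentages(self, part, whole, expected):
        assert percent(part, whole) == expected

    def test_round_half_up(self):
        assert percent(1, 8) == 12.5
        assert percent(25, 2000) == 1.25
        assert percent(1, 16) == 6.25
        assert percent(125, 10000) == 1.25  # 1.25 stays, no banker's rounding

    def test_zero_whole_rejected(self):
        with pytest.raises(ValueError):
            percent(1, 0)


def _table(records):
    df = pd.DataFrame(records, columns=["record_id", "count_A", "count_B"])
    return build_expression_table(df, total_a=10**6, total_b=10**6)


class TestTableAndCategories:
    def test_library_specific_category(self):
        table = _table([("m1", 10, 0)])
        assert table.category.tolist() == ["A_specific"]

    def test_low_expression_record_excluded_but_kept(self):
        table = _table([("m1", 0, 0)])
        assert not table.included[0]
        assert math.isnan(table.p_value[0])
        assert table.sig_label[0] == "none"

    def test_categorize_summary_percentages(self):
        records = [(f"m{i}", 5, 5) for i in range(471)]
        records += [(f"a{i}", 5, 0) for i in range(90)]
        records += [(f"b{i}", 0, 5) for i in range(56)]
        summary = categorize(_table(records))
        assert summary["n_total"] == 617
        assert summary["co_expressed"] == 471
        assert summary["co_expressed_pct"] == 76.34
        assert summary["A_specific_pct"] == 14.59
        assert summary["B_specific_pct"] == 9.08

    def test_up_down_split_among_significant(self):
        table = _table([("up", 4000, 100), ("down", 100, 4000), ("flat", 50, 50)])
        summary = categorize(table)
        assert (summary["significant"], summary["up"], summary["down"]) == (2, 1, 1)

    def test_planted_categories_recovered_exactly(self, zero_noise_run):
        truth = zero_noise_run["truth"]
        from duomir.annotate import mirna_counts_to_frame

        counts = mirna_counts_to_frame(zero_noise_run["counts"])
        df = counts.rename(
            columns={"mirna_id": "record_id", "mature_A": "count_A",
                     "mature_B": "count_B"}
        )[["record_id", "count_A", "count_B"]]
        df = df[(df.count_A > 0) | (df.count_B > 0)]
        table = build_expression_table(
            df,
            total_a=zero_noise_run["stats"]["A"].clean_total,
            total_b=zero_noise_run["stats"]["B"].clean_total,
        )
        for rec in table.itertuples(index=False):
            assert rec.category == truth.loc[rec.record_id, "category"]

    def test_bh_correction_optional(self):
        table = build_expression_table(
            pd.DataFrame({"record_id": ["a", "b"], "count_A": [500, 10],
                          "count_B": [100, 12]}),
            10**5, 10**5, bh_correction=True,
        )
        assert "q_value" in table.columns
        assert (table.q_value >= table.p_value - 1e-15).all()


class TestTopN:
    def test_single_record(self):
        table = _table([("m1", 10, 5)])
        assert top_n(table, "A", 10).record_id.tolist() == ["m1"]

    def test_descending_ne_order(self):
        table = _table([("a", 5, 1), ("b", 3, 1), ("c", 9, 1)])
        assert top_n(table, "A", 3).record_id.tolist() == ["c", "a", "b"]

    def test_rank_by_chosen_library(self):
        table = _table([("a", 5, 9), ("b", 9, 5)])
        assert top_n(table, "B", 1).record_id.tolist() == ["a"]

    def test_most_abundant_planted_mirna_tops_ranking(self, zero_noise_run):
        truth = zero_noise_run["truth"]
        counts = {mc.mirna_id: mc for mc in zero_noise_run["counts"]}
        df = pd.DataFrame(
            {
                "record_id": list(counts),
                "count_A": [counts[m].mature["A"] for m in counts],
                "count_B": [counts[m].mature["B"] for m in counts],
            }
        )
        table = build_expression_table(
            df,
            total_a=zero_noise_run["stats"]["A"].clean_total,
            total_b=zero_noise_run["stats"]["B"].clean_total,
        )
        assert top_n(table, "A", 1).record_id[0] == truth.mature_A.idxmax()
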