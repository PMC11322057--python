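"""Unit and property tests for the contingency-table statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from triadtest import (
    CountTable,
    DegenerateTableError,
    EmptyTableError,
    UndefinedStatisticError,
    collapse_genotypes,
    fisher_exact,
    hwe_test,
    logistic_odds_ratio,
    odds_ratio,
    pearson_chi2,
)
from triadtest.tables import fisher_exact_enumeration, tdt_chi2


def t22(a, b, c, d, rows=("case", "control"), cols=("B", "A")):
    return CountTable([[a, b], [c, d]], list(rows), list(cols))


class TestPearson:
    @pytest.mark.parametrize("cells, expected", [
        ((74, 74, 57, 103), 6.499),   # fetal minor-allele table
        ((56, 56, 97, 59), 3.947),    # paternal minor-allele table
    ])
    def test_uncorrected_statistic(self, cells, expected):
        res = pearson_chi2(t22(*cells))
        assert res.chi2 == pytest.approx(expected, abs=1e-3)
        assert res.df == 1

    def test_identical_rows_give_zero(self):
        res = pearson_chi2(t22(10, 20, 10, 20))
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_margin_raises(self):
        with pytest.raises(DegenerateTableError):
            pearson_chi2(t22(0, 5, 0, 7))

    @given(st.tuples(*(st.integers(0, 60) for _ in range(4))))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_closed_form(self, cells):
        """On any 2x2 table, chi2 == N(ad-bc)^2 / (r1 r2 c1 c2)."""
        a, b, c, d = cells
        r1, r2, c1, c2 = a + b, c + d, a + c, b + d
        if min(r1, r2, c1, c2) == 0:
            return
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
        assert pearson_chi2(t22(a, b, c, d)).chi2 == pytest.approx(
            closed, abs=1e-9, rel=1e-9)


class TestFisher:
    @pytest.mark.parametrize("cells, expected", [
        ((3, 1, 1, 3), 34 / 70),      # full enumeration of the support
        ((5, 0, 0, 5), 2 / 252),
        ((2, 2, 2, 2), 1.0),
    ])
    def test_two_sided_point_probability(self, cells, expected):
        assert fisher_exact(t22(*cells)).p_value == pytest.approx(
            expected, rel=1e-9)

    def test_requires_2x2(self):
        table = CountTable([[1, 2, 3], [4, 5, 6]], ["case", "control"],
                           ["x", "y", "z"])
        with pytest.raises(DegenerateTableError):
            fisher_exact(table)

    @given(st.tuples(*(st.integers(0, 12) for _ in range(4))))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_agrees_with_enumeration(self, cells):
        table = t22(*cells)
        if min(table.row_totals.min(), table.col_totals.min()) == 0:
            return
        assert fisher_exact(table).p_value == pytest.approx(
            fisher_exact_enumeration(table), rel=1e-9)


class TestOddsRatio:
    def test_fetal_minor_allele_example(self):
        res = odds_ratio(t22(74, 74, 57, 103))
        assert res.or_value == pytest.approx(1.807, abs=1e-3)
        assert res.ci_low == pytest.approx(1.144, abs=1e-3)
        assert res.ci_high == pytest.approx(2.852, abs=1e-3)
        assert not res.haldane

    def test_orientation_is_explicit(self):
        res = odds_ratio(t22(23, 125, 31, 129, cols=("T", "C")),
                         numerator_col="T", numerator_row="case")
        assert res.or_value == pytest.approx(0.765, abs=1e-3)
        assert res.ci_low == pytest.approx(0.423, abs=1e-3)
        assert res.ci_high == pytest.approx(1.385, abs=1e-3)
        assert "T in case vs control" in res.orientation

    def test_symmetric_table(self):
        res = odds_ratio(t22(50, 50, 50, 50))
        assert res.or_value == pytest.approx(1.0)
        assert res.ci_low * res.ci_high == pytest.approx(1.0)  # log-symmetric

    @given(st.tuples(*(st.integers(1, 50) for _ in range(4))))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_swap_invariance(self, cells):
        """Swapping rows AND columns leaves the OR; single swaps invert it."""
        a, b, c, d = cells
        base = odds_ratio(t22(a, b, c, d)).or_value
        both = odds_ratio(t22(d, c, b, a)).or_value
        rows_only = odds_ratio(t22(c, d, a, b)).or_value
        cols_only = odds_ratio(t22(b, a, d, c)).or_value
        assert both == pytest.approx(base, rel=1e-12)
        assert rows_only == pytest.approx(1 / base, rel=1e-12)
        assert cols_only == pytest.approx(1 / base, rel=1e-12)

    def test_zero_cell_haldane_correction(self):
        res = odds_ratio(t22(5, 0, 3, 7))
        assert res.haldane
        assert res.or_value == pytest.approx((5.5 * 7.5) / (0.5 * 3.5))

    @pytest.mark.parametrize("cells", [(12, 7, 5, 20), (30, 11, 8, 41)])
    def test_logistic_fit_equals_crude_or(self, cells):
        """A single-predictor logistic fit on the saturated 2x2 recovers the
        crude OR (cross-check of the 'multivariate regression' wording)."""
        crude = odds_ratio(t22(*cells))
        logit_or, lo, hi = logistic_odds_ratio(t22(*cells))
        assert logit_or == pytest.approx(crude.or_value, rel=1e-6)
        assert lo == pytest.approx(crude.ci_low, rel=1e-3)
        assert hi == pytest.approx(crude.ci_high, rel=1e-3)


class TestCollapse:
    def geno_table(self, case, ctrl):
        return CountTable([list(case), list(ctrl)], ["case", "control"],
                          ["CC", "CG", "GG"])

    def test_dominant_example(self):
        # fetal carrier-vs-noncarrier contrast
        table = collapse_genotypes(self.geno_table((19, 36, 19), (37, 29, 14)),
                                   "dominant")
        assert table.counts.tolist() == [[55, 19], [43, 37]]
        assert odds_ratio(table).or_value == pytest.approx(2.491, abs=1e-3)

    def test_recessive_example(self):
        table = collapse_genotypes(self.geno_table((18, 20, 18), (28, 41, 9)),
                                   "recessive")
        assert table.counts.tolist() == [[18, 38], [9, 69]]
        assert odds_ratio(table).or_value == pytest.approx(3.632, abs=1e-3)

    def test_collapse_wrt_major_swaps_homozygotes(self):
        table = collapse_genotypes(self.geno_table((13, 32, 29), (23, 34, 23)),
                                   "dominant", wrt="major")
        assert odds_ratio(table).or_value == pytest.approx(0.626, abs=1e-3)

    @given(st.tuples(*(st.integers(0, 40) for _ in range(6))),
           st.sampled_from(["dominant", "recessive"]))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_preserves_group_totals(self, cells, model):
        table = self.geno_table(cells[:3], cells[3:])
        collapsed = collapse_genotypes(table, model)
        assert collapsed.row_totals.tolist() == table.row_totals.tolist()

    def test_degenerate_monomorphic_column(self):
        table = collapse_genotypes(self.geno_table((10, 0, 0), (12, 0, 0)),
                                   "dominant")
        assert table.column("CG+GG").tolist() == [0, 0]


class TestHWE:
    def test_exact_proportions_give_zero(self):
        assert hwe_test((25, 50, 25)).chi2 == pytest.approx(0.0)

    def test_excess_homozygosity(self):
        # hand evaluation: expected (25, 50, 25) at p-hat = 0.5
        res = hwe_test((30, 40, 30))
        assert res.chi2 == pytest.approx(4.0)
        assert res.p_value == pytest.approx(0.0455, abs=2e-4)
        assert res.df == 1
        assert sum(res.expected) == pytest.approx(100)

    def test_monomorphic_flagged(self):
        res = hwe_test((0, 0, 50))
        assert res.monomorphic
        assert res.chi2 == 0.0
        assert res.minor_freq == 1.0

    def test_empty_raises(self):
        with pytest.raises(EmptyTableError):
            hwe_test((0, 0, 0))

    @given(st.integers(1, 40), st.integers(1, 40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_zero_iff_het_squared_matches(self, naa, nbb):
        """chi2 == 0 whenever AB^2 == 4 AA BB (exact HW proportions)."""
        nab2 = 4 * naa * nbb
        nab = math.isqrt(nab2)
        if nab * nab != nab2:
            return
        assert hwe_test((naa, nab, nbb)).chi2 == pytest.approx(0.0, abs=1e-9)


def test_tdt_chi2_undefined_for_no_transmissions():
    with pytest.raises(UndefinedStatisticError):
        tdt_chi2(0, 0)
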