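"""Contingency tables and the elementary association statistics.

Everything downstream (allelic/genotypic case-control tests, the combined
maternal-fetal analysis, the reproduction auditor) reduces to a handful of
operations on small integer tables:

* Pearson's chi-square without continuity correction,
* Fisher's exact test (two-sided, point-probability method),
* the odds ratio with a Woolf (log-scale Wald) 95% CI,
* genotype-model collapsing (dominant / recessive), and
* the Hardy-Weinberg goodness-of-fit test.

Pearson and Fisher delegate to scipy; the odds ratio and its CI delegate to
``statsmodels.stats.contingency_tables.Table2x2`` (whose CI is exactly the
Woolf interval exp(ln OR +/- z * sqrt(sum 1/n_ij))).  Tables containing a
zero cell get the Haldane-Anscombe +0.5 correction before the OR is formed,
and the result is flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import Table2x2

from .errors import DegenerateTableError, EmptyTableError, UndefinedStatisticError

class CountTable:
    """A groups x categories table of non-negative integer counts."""

    def __init__(self, counts: Sequence[Sequence[int]] | np.ndarray,
                 row_labels: Sequence[str], col_labels: Sequence[str]):
        arr = np.asarray(counts)
        if arr.ndim != 2:
            raise DegenerateTableError("counts must be two-dimensional")
        if arr.shape != (len(row_labels), len(col_labels)):
            raise DegenerateTableError(
                f"counts shape {arr.shape} does not match labels "
                f"({len(row_labels)} x {len(col_labels)})")
        if np.any(arr < 0) or not np.all(arr == arr.astype(int)):
            raise DegenerateTableError("counts must be non-negative integers")
        self.counts = arr.astype(int)
        self.row_labels = list(row_labels)
        self.col_labels = list(col_labels)

    # -- construction helpers -------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        return cls(df.to_numpy(), [str(i) for i in df.index],
                   [str(c) for c in df.columns])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels,
                            columns=self.col_labels)

    # -- margins --------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row(self, label: str) -> np.ndarray:
        return self.counts[self.row_labels.index(label)]

    def column(self, label: str) -> np.ndarray:
        return self.counts[:, self.col_labels.index(label)]

    def reorder(self, row_labels: Sequence[str] | None = None,
                col_labels: Sequence[str] | None = None) -> "CountTable":
        rows = [self.row_labels.index(r) for r in (row_labels or self.row_labels)]
        cols = [self.col_labels.index(c) for c in (col_labels or self.col_labels)]
        return CountTable(self.counts[np.ix_(rows, cols)],
                          [self.row_labels[i] for i in rows],
                          [self.col_labels[j] for j in cols])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CountTable(\n{self.to_dataframe()}\n)"


@dataclass
class AssocResult:
    """Association-test output: OR with 95% CI, test statistic and p-value.

    ``orientation`` records which category (column) and which group (row)
    form the numerator of the odds ratio, so the direction of every reported
    OR is explicit.  ``haldane`` marks estimates computed after the +0.5
    zero-cell correction.
    """

    or_value: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    chi2: float | None = None
    df: int | None = None
    p_value: float | None = None
    test: str | None = None
    orientation: str | None = None
    haldane: bool = False

    def as_dict(self) -> dict:
        return {
            "OR": self.or_value, "CI95_low": self.ci_low, "CI95_high": self.ci_high,
            "chi2": self.chi2, "df": self.df, "p": self.p_value,
            "test": self.test, "orientation": self.orientation,
            "haldane": self.haldane,
        }


@dataclass
class HWEResult:
    """Hardy-Weinberg goodness-of-fit result for one group at one locus."""

    chi2: float
    p_value: float
    observed: tuple[int, int, int]
    expected: tuple[float, float, float]
    minor_freq: float
    df: int = 1
    monomorphic: bool = False


def expected_counts(table: CountTable) -> np.ndarray:
    """Expected cell counts under row/column independence."""
    return np.outer(table.row_totals, table.col_totals) / table.total


def pearson_chi2(table: CountTable) -> AssocResult:
    """Uncorrected Pearson chi-square test on an r x c table."""
    if np.any(table.row_totals == 0) or np.any(table.col_totals == 0):
        raise DegenerateTableError("table has a zero row or column margin")
    exp = expected_counts(table)
    if np.any(exp <= 0):
        raise DegenerateTableError("all expected counts must be positive")
    chi2, p, dof, _ = stats.chi2_contingency(table.counts, correction=False)
    return AssocResult(chi2=float(chi2), df=int(dof), p_value=float(p),
                       test="pearson")


def fisher_exact(table: CountTable) -> AssocResult:
    """Two-sided Fisher exact test on a 2x2 table.

    The p-value is the sum of hypergeometric probabilities of all tables
    with the observed margins whose probability does not exceed that of the
    observed table (point-probability method).
    """
    if table.shape != (2, 2):
        raise DegenerateTableError(
            f"Fisher's exact test requires a 2x2 table, got {table.shape}")
    _, p = stats.fisher_exact(table.counts, alternative="two-sided")
    return AssocResult(p_value=float(p), test="fisher")


def odds_ratio(table: CountTable,
               numerator_col: str | None = None,
               numerator_row: str | None = None) -> AssocResult:
    """Odds ratio of a 2x2 table with the Woolf 95% CI and Wald p-value.

    ``numerator_col``/``numerator_row`` select the category and the group
    forming the OR numerator (defaults: first column, first row).  Any zero
    cell triggers the Haldane-Anscombe +0.5 correction, flagged in the
    result.
    """
    if table.shape != (2, 2):
        raise DegenerateTableError(
            f"odds ratio requires a 2x2 table, got {table.shape}")
    oriented = table.reorder(
        row_labels=_front(table.row_labels, numerator_row),
        col_labels=_front(table.col_labels, numerator_col),
    )
    counts = oriented.counts.astype(float)
    haldane = bool(np.any(counts == 0))
    if haldane:
        counts = counts + 0.5
    t22 = Table2x2(counts, shift_zeros=False)
    lo, hi = t22.oddsratio_confint(alpha=0.05)
    return AssocResult(
        or_value=float(t22.oddsratio),
        ci_low=float(lo), ci_high=float(hi),
        p_value=float(t22.oddsratio_pvalue()),
        test="wald",
        orientation=(f"{oriented.col_labels[0]} in {oriented.row_labels[0]} "
                     f"vs {oriented.row_labels[1]}"),
        haldane=haldane,
    )


def _front(labels: list[str], chosen: str | None) -> list[str]:
    if chosen is None:
        return labels
    if chosen not in labels:
        raise DegenerateTableError(f"label {chosen!r} not in {labels}")
    rest = [x for x in labels if x != chosen]
    return [chosen] + rest


def collapse_genotypes(table: CountTable, model: str,
                       wrt: str = "minor") -> CountTable:
    """Collapse a 2x3 genotype table (major-hom, het, minor-hom) to 2x2.

    ``model='dominant'`` contrasts carriers of the reference allele against
    non-carriers; ``model='recessive'`` contrasts homozygotes for it against
    everyone else.  ``wrt`` chooses the reference allele: ``'minor'`` (the
    usual mutant-allele convention) or ``'major'``.
    """
    if table.shape[1] != 3:
        raise DegenerateTableError(
            f"genotype collapsing needs 3 genotype columns, got {table.shape[1]}")
    aa, ab, bb = (table.counts[:, i] for i in range(3))
    l_aa, l_ab, l_bb = table.col_labels
    if wrt == "major":  # swap the roles of the two homozygote classes
        aa, bb = bb, aa
        l_aa, l_bb = l_bb, l_aa
    elif wrt != "minor":
        raise DegenerateTableError(f"wrt must be 'minor' or 'major', got {wrt!r}")
    if model == "dominant":
        cols = np.column_stack([ab + bb, aa])
        labels = [f"{l_ab}+{l_bb}", l_aa]
    elif model == "recessive":
        cols = np.column_stack([bb, aa + ab])
        labels = [l_bb, f"{l_aa}+{l_ab}"]
    else:
        raise DegenerateTableError(
            f"model must be 'dominant' or 'recessive', got {model!r}")
    return CountTable(cols, table.row_labels, labels)


def hwe_test(genotype_counts: Sequence[int]) -> HWEResult:
    """Pearson goodness-of-fit test of Hardy-Weinberg proportions.

    ``genotype_counts`` are (major-hom, het, minor-hom) counts for a single
    group.  The allele frequency is estimated from the counts themselves, so
    the chi-square has one degree of freedom (3 classes - 1 - 1 estimated
    parameter).  A monomorphic sample is returned with chi2 = 0 and flagged.
    """
    n_aa, n_ab, n_bb = (int(c) for c in genotype_counts)
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise EmptyTableError("no genotyped individuals for HWE test")
    q = (2 * n_bb + n_ab) / (2 * n)  # minor-allele frequency
    p = 1.0 - q
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    observed = (n_aa, n_ab, n_bb)
    if q == 0.0 or q == 1.0:
        return HWEResult(chi2=0.0, p_value=1.0, observed=observed,
                         expected=expected, minor_freq=q, monomorphic=True)
    chi2 = float(sum((o - e) ** 2 / e for o, e in zip(observed, expected)))
    return HWEResult(chi2=chi2, p_value=float(stats.chi2.sf(chi2, 1)),
                     observed=observed, expected=expected, minor_freq=q)


def logistic_odds_ratio(table: CountTable) -> tuple[float, float, float]:
    """Single-predictor logistic-regression OR for a 2x2 table (cross-check).

    Fits logit P(group = first row) = b0 + b1 * 1[category = first column]
    by IRLS (statsmodels GLM); on a saturated 2x2 the fitted exp(b1) equals
    the crude odds ratio.  Returns (OR, CI_low, CI_high).
    """
    import statsmodels.api as sm

    if table.shape != (2, 2):
        raise DegenerateTableError("logistic cross-check requires a 2x2 table")
    # one weighted observation per cell
    y = np.array([1.0, 1.0, 0.0, 0.0])          # group indicator (first row)
    x = np.array([1.0, 0.0, 1.0, 0.0])          # category indicator (first col)
    w = table.counts.reshape(-1).astype(float)
    X = sm.add_constant(x)
    fit = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w).fit(
        tol=1e-10)
    lo, hi = fit.conf_int()[1]
    return float(math.exp(fit.params[1])), float(math.exp(lo)), float(math.exp(hi))


def fisher_exact_enumeration(table: CountTable) -> float:
    """Brute-force two-sided Fisher p by enumerating the hypergeometric support.

    Independent of :func:`fisher_exact`; intended as a test oracle for small
    tables.
    """
    if table.shape != (2, 2):
        raise DegenerateTableError("enumeration oracle requires a 2x2 table")
    a, b = int(table.counts[0, 0]), int(table.counts[0, 1])
    c, d = int(table.counts[1, 0]), int(table.counts[1, 1])
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {k: (math.comb(c1, k) * math.comb(n - c1, r1 - k)) / math.comb(n, r1)
             for k in range(lo, hi + 1)}
    p_obs = probs[a]
    # scipy-style tolerance for float ties on "<= observed probability"
    return float(sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9)))


def tdt_chi2(a: float, b: float) -> float:
    """The TDT statistic (a - b)^2 / (a + b)."""
    if a + b <= 0:
        raise UndefinedStatisticError("TDT undefined: no informative transmissions")
    return (a - b) ** 2 / (a + b)
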