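"""Case-control allelic and genotypic association analyses.

The counting conventions mirror the usual candidate-gene workflow: each
genotyped individual of a given role (mother / father / offspring)
contributes two alleles to the allelic table, or one genotype to the
genotypic table, and families are excluded *per locus* when that member is
untyped there (complete-case by locus, so the effective N may differ across
loci and roles).

Tests follow the classic recipe: uncorrected Pearson chi-square, or
Fisher's exact test when any expected cell is below 5 (``test="auto"``);
odds ratios are crude (unadjusted), with the Woolf 95% CI.  A
single-predictor logistic fit is available as a cross-check and is provably
identical to the crude OR on a saturated 2x2 table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort, Locus, ROLES
from .errors import EmptyTableError, ValidationError
from .tables import (
    AssocResult,
    CountTable,
    collapse_genotypes,
    expected_counts,
    fisher_exact,
    odds_ratio,
    pearson_chi2,
)

GROUPS = ("case", "control")


def _minor_counts(cohort: Cohort, locus: Locus, role: str, status: str):
    """Yield the number of minor alleles per typed individual of a role/status."""
    if role not in ROLES:
        raise ValidationError(f"role must be one of {ROLES}, got {role!r}")
    for fam in cohort.families_with_status(status):
        k = locus.minor_count(fam.genotype(role, locus.rsid))
        if k is not None:
            yield k


def allele_count_table(cohort: Cohort, locus: Locus | str,
                       role: str = "offspring") -> CountTable:
    """2x2 allele-count table (rows case/control, columns minor/major)."""
    locus = cohort.locus(locus) if isinstance(locus, str) else locus
    rows = []
    for status in GROUPS:
        ks = list(_minor_counts(cohort, locus, role, status))
        minor = sum(ks)
        rows.append([minor, 2 * len(ks) - minor])
    if sum(r[0] + r[1] for r in rows) == 0:
        raise EmptyTableError(
            f"no genotyped {role}s at {locus.rsid} in either group")
    return CountTable(rows, list(GROUPS), [locus.minor, locus.major])


def genotype_count_table(cohort: Cohort, locus: Locus | str,
                         role: str = "offspring") -> CountTable:
    """2x3 genotype-count table (columns major-hom, het, minor-hom)."""
    locus = cohort.locus(locus) if isinstance(locus, str) else locus
    rows = []
    for status in GROUPS:
        counts = [0, 0, 0]
        for k in _minor_counts(cohort, locus, role, status):
            counts[k] += 1
        rows.append(counts)
    if sum(sum(r) for r in rows) == 0:
        raise EmptyTableError(
            f"no genotyped {role}s at {locus.rsid} in either group")
    return CountTable(rows, list(GROUPS), list(locus.genotype_labels()))


def minor_allele_frequencies(table: CountTable) -> dict[str, float]:
    """Per-group minor-allele frequency from a 2x2 allele table."""
    return {
        grp: table.counts[i, 0] / table.counts[i].sum()
        for i, grp in enumerate(table.row_labels)
    }


def choose_test(table: CountTable, test: str = "auto") -> str:
    """Resolve 'auto' to 'fisher' when any expected count is below 5."""
    if test in ("pearson", "fisher"):
        return test
    if test != "auto":
        raise ValidationError(f"test must be auto|pearson|fisher, got {test!r}")
    return "fisher" if (table.shape == (2, 2)
                        and np.any(expected_counts(table) < 5)) else "pearson"


def _run_test(table: CountTable, test: str) -> AssocResult:
    return fisher_exact(table) if test == "fisher" else pearson_chi2(table)


def _merge(or_res: AssocResult, test_res: AssocResult) -> AssocResult:
    """Combine an OR estimate with an independence-test result."""
    return AssocResult(
        or_value=or_res.or_value, ci_low=or_res.ci_low, ci_high=or_res.ci_high,
        chi2=test_res.chi2, df=test_res.df, p_value=test_res.p_value,
        test=test_res.test, orientation=or_res.orientation,
        haldane=or_res.haldane,
    )


@dataclass
class AssociationResults:
    """Fitted case-control association for one locus/role.

    Attributes
    ----------
    table : CountTable
        The counts the statistics were computed from.
    result : AssocResult
        OR, Woolf CI, test statistic and p-value.
    """

    rsid: str
    gene: str
    role: str
    level: str            # 'allele' | 'genotype' | 'dominant' | 'recessive'
    table: CountTable
    result: AssocResult

    def summary(self) -> str:
        df = self.table.to_dataframe()
        r = self.result
        plural = {"mother": "mothers", "father": "fathers",
                  "offspring": "offspring"}[self.role]
        lines = [
            f"{self.level.capitalize()} association at {self.rsid} "
            f"({self.gene}), {plural}",
            df.to_string(),
        ]
        if r.or_value is not None:
            lines.append(
                f"OR = {r.or_value:.3f} (95% CI {r.ci_low:.3f}-{r.ci_high:.3f})"
                f"  [{r.orientation}]" + ("  (+0.5 zero-cell)" if r.haldane else ""))
        if r.chi2 is not None:
            lines.append(f"chi2 = {r.chi2:.3f} (df={r.df}), p = {r.p_value:.4g}"
                         f"  [{r.test}]")
        else:
            lines.append(f"p = {r.p_value:.4g}  [{r.test}]")
        return "\n".join(lines)

    def row(self) -> dict:
        d = {"rsid": self.rsid, "gene": self.gene, "role": self.role,
             "level": self.level}
        for grp, cnts in zip(self.table.row_labels, self.table.counts):
            for lab, c in zip(self.table.col_labels, cnts):
                d[f"{grp}_{lab}"] = int(c)
        d.update(self.result.as_dict())
        return d


class AllelicAssociation:
    """Case-control allelic association model for one locus and role.

    Parameters
    ----------
    cohort : Cohort
    locus : Locus or rsid
    role : which family member's genotypes are compared ('mother',
        'father' or 'offspring').
    """

    def __init__(self, cohort: Cohort, locus: Locus | str,
                 role: str = "offspring"):
        self.cohort = cohort
        self.locus = cohort.locus(locus) if isinstance(locus, str) else locus
        self.role = role
        self.table = allele_count_table(cohort, self.locus, role)

    def fit(self, test: str = "auto",
            orient: str = "minor") -> AssociationResults:
        """Run the test and OR.

        ``orient`` names the numerator allele of the OR: 'minor', 'major'
        or an explicit allele symbol.
        """
        numerator = {"minor": self.locus.minor,
                     "major": self.locus.major}.get(orient, orient)
        if numerator not in self.locus.alleles:
            raise ValidationError(
                f"orient {orient!r} is not an allele of {self.locus.rsid}")
        or_res = odds_ratio(self.table, numerator_col=numerator,
                            numerator_row="case")
        test_res = _run_test(self.table, choose_test(self.table, test))
        return AssociationResults(
            rsid=self.locus.rsid, gene=self.locus.gene, role=self.role,
            level="allele", table=self.table, result=_merge(or_res, test_res))


class GenotypicAssociation:
    """Case-control genotypic association, optionally under a genetic model.

    With ``model=None`` the full 2x3 genotype table is tested (no OR).  With
    ``model='dominant'`` or ``'recessive'`` the table is collapsed with
    respect to ``wrt`` ('minor' by default) and a 2x2 OR + test is computed.
    """

    def __init__(self, cohort: Cohort, locus: Locus | str,
                 role: str = "offspring", model: str | None = None,
                 wrt: str = "minor"):
        self.cohort = cohort
        self.locus = cohort.locus(locus) if isinstance(locus, str) else locus
        self.role = role
        self.model = model
        self.wrt = wrt
        self.genotype_table = genotype_count_table(cohort, self.locus, role)
        self.table = (self.genotype_table if model is None else
                      collapse_genotypes(self.genotype_table, model, wrt=wrt))

    def fit(self, test: str = "auto") -> AssociationResults:
        level = self.model or "genotype"
        if self.model is None:
            test_res = _run_test(self.table,
                                 "pearson" if test == "auto" else test)
            result = test_res
        else:
            or_res = odds_ratio(self.table, numerator_row="case")
            test_res = _run_test(self.table, choose_test(self.table, test))
            result = _merge(or_res, test_res)
        return AssociationResults(
            rsid=self.locus.rsid, gene=self.locus.gene, role=self.role,
            level=level, table=self.table, result=result)


def association_scan(cohort: Cohort, role: str = "offspring",
                     level: str = "allele", model: str | None = None,
                     test: str = "auto") -> pd.DataFrame:
    """Run one association per locus and stack the results in a DataFrame."""
    rows = []
    for locus in cohort.loci:
        try:
            if level == "allele":
                res = AllelicAssociation(cohort, locus, role).fit(test=test)
            else:
                res = GenotypicAssociation(cohort, locus, role,
                                           model=model).fit(test=test)
        except EmptyTableError:
            continue
        rows.append(res.row())
    return pd.DataFrame(rows)
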