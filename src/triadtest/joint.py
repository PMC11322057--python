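"""Maternal-locus x fetal-locus combined-genotype association.

Mothers and offspring are each collapsed to two classes at their own locus
(carrier / non-carrier under a dominant model, or homozygote / rest under a
recessive model), giving K = 4 combination categories.  The 2xK
case-control table is tested globally with Pearson's chi-square (df = K-1),
and each category is contrasted against a reference category (by default
the one with the highest combined incidence) as a 2x2 odds ratio with the
Woolf CI and Wald p -- on a saturated table these crude ORs coincide with
the coefficients of a logistic regression on category indicators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort, Genotype, Locus
from .errors import EmptyTableError, ValidationError
from .tables import AssocResult, CountTable, odds_ratio, pearson_chi2

GROUPS = ("case", "control")


def genotype_class(locus: Locus, gt: Genotype, model: str) -> str | None:
    """Collapse one genotype to its two-class label (None if missing).

    dominant:  '<het>/<minor-hom>' (carrier) vs '<major-hom>'
    recessive: '<minor-hom>' vs '<major-hom>/<het>'
    """
    labels = class_labels(locus, model)
    k = locus.minor_count(gt)
    if k is None:
        return None
    if model == "dominant":
        return labels[1] if k >= 1 else labels[0]
    if model == "recessive":
        return labels[1] if k == 2 else labels[0]
    raise ValidationError(f"model must be dominant|recessive, got {model!r}")


def class_labels(locus: Locus, model: str) -> tuple[str, str]:
    """(non-risk class, risk class) labels for a collapsing model."""
    aa, ab, bb = locus.genotype_labels()
    if model == "dominant":
        return (aa, f"{ab}/{bb}")
    if model == "recessive":
        return (f"{aa}/{ab}", bb)
    raise ValidationError(f"model must be dominant|recessive, got {model!r}")


def combo_table(cohort: Cohort, maternal_locus: Locus | str,
                maternal_model: str, fetal_locus: Locus | str,
                fetal_model: str) -> CountTable:
    """2xK table of maternal-class x fetal-class counts by case status.

    Categories are labelled '<maternal class>|<fetal class>' and partition
    all mother-offspring pairs typed at both loci; empty categories are
    retained with zero counts.
    """
    m_locus = (cohort.locus(maternal_locus)
               if isinstance(maternal_locus, str) else maternal_locus)
    f_locus = (cohort.locus(fetal_locus)
               if isinstance(fetal_locus, str) else fetal_locus)
    m_classes = class_labels(m_locus, maternal_model)
    f_classes = class_labels(f_locus, fetal_model)
    categories = [f"{mc}|{fc}" for mc in m_classes for fc in f_classes]
    rows = []
    for status in GROUPS:
        counts = dict.fromkeys(categories, 0)
        for fam in cohort.families_with_status(status):
            mc = genotype_class(m_locus, fam.mother.get(m_locus.rsid),
                                maternal_model)
            fc = genotype_class(f_locus, fam.offspring.get(f_locus.rsid),
                                fetal_model)
            if mc is None or fc is None:
                continue
            counts[f"{mc}|{fc}"] += 1
        rows.append([counts[c] for c in categories])
    table = CountTable(rows, list(GROUPS), categories)
    if table.total == 0:
        raise EmptyTableError("no complete mother-offspring pairs at both loci")
    return table


def combo_global_test(table: CountTable) -> AssocResult:
    """Pearson chi-square heterogeneity test on the 2xK combination table."""
    if table.shape[0] != 2 or table.shape[1] < 2:
        raise ValidationError(
            f"global combination test needs a 2xK table (K>=2), got {table.shape}")
    return pearson_chi2(table)


def combo_reference_ors(table: CountTable,
                        reference: str = "auto") -> "ComboResults":
    """Odds ratio of each combination category against a reference category.

    ``reference='auto'`` picks the category with the largest combined
    (case + control) count.  Categories with a zero cell get the
    Haldane-Anscombe correction and are flagged.
    """
    if reference == "auto":
        reference = table.col_labels[int(np.argmax(table.col_totals))]
    if reference not in table.col_labels:
        raise ValidationError(
            f"reference {reference!r} not among categories {table.col_labels}")
    per_category: dict[str, AssocResult | None] = {}
    for cat in table.col_labels:
        if cat == reference:
            per_category[cat] = None
            continue
        sub = CountTable(
            np.column_stack([table.column(cat), table.column(reference)]),
            table.row_labels, [cat, reference])
        per_category[cat] = odds_ratio(sub, numerator_col=cat,
                                       numerator_row="case")
    return ComboResults(table=table, reference=reference,
                        global_test=combo_global_test(table),
                        category_ors=per_category)


@dataclass
class ComboResults:
    """Fitted maternal x fetal combined-genotype association."""

    table: CountTable
    reference: str
    global_test: AssocResult
    category_ors: dict[str, AssocResult | None]

    def summary(self) -> str:
        g = self.global_test
        lines = [
            "Maternal x fetal genotype-combination association",
            self.table.to_dataframe().T.to_string(),
            f"global chi2 = {g.chi2:.3f} (df={g.df}), p = {g.p_value:.4g}",
            f"reference category: {self.reference}",
        ]
        for cat, r in self.category_ors.items():
            if r is None:
                lines.append(f"  {cat}: reference")
            else:
                flag = "  (+0.5 zero-cell)" if r.haldane else ""
                lines.append(
                    f"  {cat}: OR = {r.or_value:.3f} "
                    f"(95% CI {r.ci_low:.3f}-{r.ci_high:.3f}), "
                    f"p = {r.p_value:.4g}{flag}")
        return "\n".join(lines)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, cat in enumerate(self.table.col_labels):
            r = self.category_ors[cat]
            rows.append({
                "category": cat,
                "case": int(self.table.counts[0, i]),
                "control": int(self.table.counts[1, i]),
                "OR": None if r is None else r.or_value,
                "CI95_low": None if r is None else r.ci_low,
                "CI95_high": None if r is None else r.ci_high,
                "p": None if r is None else r.p_value,
                "reference": cat == self.reference,
            })
        return pd.DataFrame(rows)


class MaternalFetalCombination:
    """Model for the maternal x fetal combined-genotype analysis.

    Builds the 2xK combination table from the cohort and, on ``fit``,
    computes the global heterogeneity test plus reference-category odds
    ratios.
    """

    def __init__(self, cohort: Cohort, maternal_locus: Locus | str,
                 fetal_locus: Locus | str, maternal_model: str = "dominant",
                 fetal_model: str = "dominant"):
        self.cohort = cohort
        self.maternal_locus = (cohort.locus(maternal_locus)
                               if isinstance(maternal_locus, str)
                               else maternal_locus)
        self.fetal_locus = (cohort.locus(fetal_locus)
                            if isinstance(fetal_locus, str) else fetal_locus)
        self.maternal_model = maternal_model
        self.fetal_model = fetal_model
        self.table = combo_table(cohort, self.maternal_locus, maternal_model,
                                 self.fetal_locus, fetal_model)

    def fit(self, reference: str = "auto") -> ComboResults:
        return combo_reference_ors(self.table, reference=reference)
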