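"""Transmission disequilibrium test (TDT) on family triads.

For each complete, Mendelian-consistent triad the transmitted and
untransmitted allele of each parent is inferred by subtracting the other
parent's forced contribution from the offspring genotype.  Only
*informative* (heterozygous) parents enter the statistic

    chi2 = (a - b)^2 / (a + b),   df = 1,

where ``a`` counts transmissions of the allele of interest and ``b``
non-transmissions, compared against the Mendelian null of equal
transmission.

When both parents and the offspring are all heterozygous, the pair of
transmissions is necessarily one copy of each allele but *which parent*
transmitted which cannot be resolved; such records are marked ambiguous.
They always contribute one transmission of each allele to the overall
(parent-of-origin-agnostic) stratum; for the mother/father strata an
``ambiguity`` policy applies: ``'exclude'`` (default) drops them from the
parental strata and reports their number, ``'split'`` credits half a
transmission of each allele to each parent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from scipy import stats

from .cohort import Cohort, Family, Locus, genotype, trio_consistent
from .errors import (
    MendelianInconsistencyError,
    UndefinedStatisticError,
    ValidationError,
)
from .tables import tdt_chi2

STRATA = ("all", "mother", "father")
AMBIGUITY_POLICIES = ("exclude", "split")


@dataclass(frozen=True)
class TransmissionRecord:
    """One parent's transmission at one locus in one family."""

    family_id: str
    rsid: str
    parent: str                      # 'mother' | 'father'
    transmitted: str | None          # allele symbol; None if ambiguous
    untransmitted: str | None
    informative: bool                # parent heterozygous
    ambiguous: bool = False          # double-het triad with het offspring


@dataclass
class TDTResult:
    """TDT counts and statistic for one stratum.

    ``a``/``b`` are transmission counts of the allele of interest / the
    other allele from informative parents (floats: the 'split' ambiguity
    policy credits halves).
    """

    stratum: str
    allele: str
    a: float
    b: float
    chi2: float | None
    p_value: float | None
    n_ambiguous: int = 0
    df: int = 1

    @classmethod
    def from_counts(cls, a: float, b: float, stratum: str = "all",
                    allele: str = "", n_ambiguous: int = 0) -> "TDTResult":
        if a < 0 or b < 0:
            raise ValidationError("transmission counts must be non-negative")
        chi2 = tdt_chi2(a, b)
        return cls(stratum=stratum, allele=allele, a=a, b=b, chi2=chi2,
                   p_value=float(stats.chi2.sf(chi2, 1)),
                   n_ambiguous=n_ambiguous)


def tdt_statistic(a: float, b: float, stratum: str = "all",
                  allele: str = "") -> TDTResult:
    """TDT chi-square from transmitted/untransmitted counts ``a`` and ``b``."""
    return TDTResult.from_counts(a, b, stratum=stratum, allele=allele)


def infer_transmissions(family: Family, locus: Locus) -> list[TransmissionRecord]:
    """Infer each parent's transmitted allele in one triad at one locus.

    Requires a complete triad; dyads yield no records.  Raises
    :class:`MendelianInconsistencyError` when the offspring genotype is
    impossible given the parents.
    """
    rsid = locus.rsid
    if family.father is None:
        return []
    m, f, c = (family.mother.get(rsid), family.father.get(rsid),
               family.offspring.get(rsid))
    if m is None or f is None or c is None:
        return []
    if not trio_consistent(m, f, c):
        raise MendelianInconsistencyError(
            f"family {family.family_id} at {rsid}: offspring {''.join(c)} "
            f"impossible from {''.join(m)} x {''.join(f)}")
    # all (maternal, paternal) assignments consistent with the offspring
    assignments = {(ma, fa) for ma in m for fa in f
                   if genotype(ma, fa) == c}
    maternal = {ma for ma, _ in assignments}
    paternal = {fa for _, fa in assignments}
    records = []
    for parent, gt, transmitted_set in (("mother", m, maternal),
                                        ("father", f, paternal)):
        informative = gt[0] != gt[1]
        if len(transmitted_set) == 1:
            t = next(iter(transmitted_set))
            u = gt[1] if gt[0] == t else gt[0]
            records.append(TransmissionRecord(
                family.family_id, rsid, parent, t, u, informative))
        else:
            # both parents het, offspring het: one copy of each allele was
            # transmitted overall, but parent-of-origin is unresolvable
            records.append(TransmissionRecord(
                family.family_id, rsid, parent, None, None, informative,
                ambiguous=True))
    return records


def collect_transmissions(cohort: Cohort, locus: Locus | str,
                          status: str) -> tuple[list[TransmissionRecord], list[str]]:
    """Transmission records for all complete triads of a status.

    Families that fail the Mendelian check at this locus are skipped (they
    are uninterpretable for transmission counting) and their IDs returned.
    """
    locus = cohort.locus(locus) if isinstance(locus, str) else locus
    records: list[TransmissionRecord] = []
    skipped: list[str] = []
    for fam in cohort.families_with_status(status):
        try:
            records.extend(infer_transmissions(fam, locus))
        except MendelianInconsistencyError:
            skipped.append(fam.family_id)
    return records, skipped


def count_transmissions(records: Iterable[TransmissionRecord], allele: str,
                        stratum: str = "all",
                        ambiguity: str = "exclude") -> tuple[float, float, int]:
    """Tally (a, b, n_ambiguous) over informative records for one stratum."""
    if ambiguity not in AMBIGUITY_POLICIES:
        raise ValidationError(
            f"ambiguity must be one of {AMBIGUITY_POLICIES}, got {ambiguity!r}")
    a = b = 0.0
    n_amb = 0
    for rec in records:
        if not rec.informative:
            continue
        if stratum != "all" and rec.parent != stratum:
            continue
        if rec.ambiguous:
            n_amb += 1
            if stratum == "all":
                # the ambiguous *pair* transmits one copy of each allele;
                # each of its two records contributes half of that pair
                a += 0.5
                b += 0.5
            elif ambiguity == "split":
                a += 0.5
                b += 0.5
        else:
            if rec.transmitted == allele:
                a += 1.0
            else:
                b += 1.0
    return a, b, n_amb


class TransmissionDisequilibriumTest:
    """TDT model for one locus, restricted to triads of one status.

    Parameters
    ----------
    cohort, locus : the data and the SNP to test.
    status : 'case' or 'control' -- the TDT is always run within one arm,
        never pooled.
    allele : allele of interest, 'minor' (default), 'major' or a symbol.
    ambiguity : parental-stratum policy for double-heterozygous triads,
        'exclude' (default) or 'split'.
    """

    def __init__(self, cohort: Cohort, locus: Locus | str, status: str,
                 allele: str = "minor", ambiguity: str = "exclude"):
        self.cohort = cohort
        self.locus = cohort.locus(locus) if isinstance(locus, str) else locus
        self.status = status
        self.ambiguity = ambiguity
        self.allele = {"minor": self.locus.minor,
                       "major": self.locus.major}.get(allele, allele)
        if self.allele not in self.locus.alleles:
            raise ValidationError(
                f"allele {allele!r} is not an allele of {self.locus.rsid}")
        self.records, self.skipped_families = collect_transmissions(
            cohort, self.locus, status)

    def fit(self) -> "TDTResults":
        by_stratum: dict[str, TDTResult] = {}
        for stratum in STRATA:
            a, b, n_amb = count_transmissions(
                self.records, self.allele, stratum, self.ambiguity)
            if a + b > 0:
                by_stratum[stratum] = TDTResult.from_counts(
                    a, b, stratum=stratum, allele=self.allele,
                    n_ambiguous=n_amb)
            else:
                by_stratum[stratum] = TDTResult(
                    stratum=stratum, allele=self.allele, a=a, b=b,
                    chi2=None, p_value=None, n_ambiguous=n_amb)
        if by_stratum["all"].chi2 is None:
            raise UndefinedStatisticError(
                f"no informative transmissions at {self.locus.rsid} in "
                f"{self.status} triads")
        n_informative = sum(1 for r in self.records if r.informative)
        return TDTResults(
            rsid=self.locus.rsid, status=self.status, allele=self.allele,
            ambiguity=self.ambiguity, strata=by_stratum,
            n_informative=n_informative,
            n_skipped_mendel=len(self.skipped_families))


@dataclass
class TDTResults:
    """Fitted TDT with per-stratum counts and statistics."""

    rsid: str
    status: str
    allele: str
    ambiguity: str
    strata: dict[str, TDTResult]
    n_informative: int
    n_skipped_mendel: int

    @property
    def overall(self) -> TDTResult:
        return self.strata["all"]

    @property
    def mother(self) -> TDTResult:
        return self.strata["mother"]

    @property
    def father(self) -> TDTResult:
        return self.strata["father"]

    def summary(self) -> str:
        lines = [
            f"TDT at {self.rsid}, {self.status} triads, allele of interest "
            f"{self.allele} (ambiguity policy: {self.ambiguity})",
            f"informative parental transmissions: {self.n_informative}"
            + (f"; {self.n_skipped_mendel} family(ies) skipped for Mendelian "
               f"inconsistency" if self.n_skipped_mendel else ""),
        ]
        for stratum in STRATA:
            r = self.strata[stratum]
            if r.chi2 is None:
                lines.append(f"  {stratum:6s}: no informative transmissions")
            else:
                amb = f", ambiguous records: {r.n_ambiguous}" if r.n_ambiguous else ""
                lines.append(
                    f"  {stratum:6s}: a={r.a:g} b={r.b:g}  chi2={r.chi2:.3f} "
                    f"p={r.p_value:.4g}{amb}")
        return "\n".join(lines)


def tdt_by_stratum(cohort: Cohort, locus: Locus | str, status: str,
                   allele: str = "minor",
                   ambiguity: str = "exclude") -> list[TDTResult]:
    """Functional wrapper: TDT results for the all/mother/father strata."""
    fitted = TransmissionDisequilibriumTest(
        cohort, locus, status, allele=allele, ambiguity=ambiguity).fit()
    return [fitted.strata[s] for s in STRATA]
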