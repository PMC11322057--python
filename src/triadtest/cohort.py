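"""Data model for loci, genotypes, families and cohorts.

A cohort is a collection of nuclear families, each consisting of a mother,
an optional father (families without a genotyped father are *dyads*) and one
offspring, genotyped at a shared panel of biallelic SNPs.  Family status is
binary: ``case`` (affected pregnancy) or ``control``.

Genotypes are unordered allele pairs; internally they are normalised to a
lexicographically sorted tuple so that ``("G", "A")`` and ``("A", "G")``
compare equal.  A missing genotype is ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

from .errors import ValidationError

Genotype = Optional[tuple[str, str]]

ROLES = ("mother", "father", "offspring")
STATUSES = ("case", "control")


def genotype(a1: str, a2: str) -> tuple[str, str]:
    """Normalise an unordered allele pair to its canonical (sorted) form."""
    return (a1, a2) if a1 <= a2 else (a2, a1)


@dataclass(frozen=True)
class Locus:
    """A biallelic SNP: rsID, gene label and its two allele symbols.

    ``major``/``minor`` follow the population (reference-panel) designation,
    not necessarily the sample frequencies of any particular cohort.
    """

    rsid: str
    gene: str
    major: str
    minor: str

    def __post_init__(self) -> None:
        if self.major == self.minor:
            raise ValidationError(
                f"{self.rsid}: major and minor allele must differ ({self.major!r})"
            )

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.major, self.minor))

    def genotype_labels(self) -> tuple[str, str, str]:
        """Genotype class labels ordered (major-hom, het, minor-hom)."""
        a, b = self.major, self.minor
        return (a + a, a + b, b + b)

    def minor_count(self, gt: Genotype) -> int | None:
        """Number of minor-allele copies in a genotype (None if missing)."""
        if gt is None:
            return None
        return sum(allele == self.minor for allele in gt)


@dataclass(frozen=True)
class MendelViolation:
    """A family/locus pair whose offspring genotype is impossible given the
    parental genotypes under Mendelian inheritance."""

    family_id: str
    rsid: str
    description: str


@dataclass
class Family:
    """One mother-(father)-offspring unit with per-locus genotypes.

    ``mother`` and ``offspring`` map rsID -> genotype (``None`` = failed
    genotyping at that locus).  ``father`` is ``None`` for a dyad.
    """

    family_id: str
    status: str
    mother: dict[str, Genotype]
    offspring: dict[str, Genotype]
    father: Optional[dict[str, Genotype]] = None

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValidationError(
                f"family {self.family_id}: status must be one of {STATUSES}, "
                f"got {self.status!r}"
            )

    @property
    def is_dyad(self) -> bool:
        return self.father is None

    def genotype(self, role: str, rsid: str) -> Genotype:
        if role == "mother":
            return self.mother.get(rsid)
        if role == "offspring":
            return self.offspring.get(rsid)
        if role == "father":
            return None if self.father is None else self.father.get(rsid)
        raise ValidationError(f"unknown role {role!r}; expected one of {ROLES}")

    def triad_complete(self, rsid: str) -> bool:
        """True when mother, father and offspring are all genotyped at rsid."""
        return (
            self.father is not None
            and self.mother.get(rsid) is not None
            and self.father.get(rsid) is not None
            and self.offspring.get(rsid) is not None
        )


@dataclass
class Cohort:
    """A panel of loci plus the families genotyped on it."""

    loci: list[Locus]
    families: list[Family]
    _by_rsid: dict[str, Locus] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_rsid = {}
        for locus in self.loci:
            if locus.rsid in self._by_rsid:
                raise ValidationError(f"duplicate locus {locus.rsid}")
            self._by_rsid[locus.rsid] = locus
        seen_fids: set[str] = set()
        for fam in self.families:
            if fam.family_id in seen_fids:
                raise ValidationError(f"duplicate family ID {fam.family_id}")
            seen_fids.add(fam.family_id)
            self._validate_family(fam)

    def _validate_family(self, fam: Family) -> None:
        members = [("mother", fam.mother), ("offspring", fam.offspring)]
        if fam.father is not None:
            members.append(("father", fam.father))
        for role, genos in members:
            for rsid, gt in genos.items():
                locus = self._by_rsid.get(rsid)
                if locus is None:
                    raise ValidationError(
                        f"family {fam.family_id} {role}: genotype at undeclared "
                        f"locus {rsid}"
                    )
                if gt is None:
                    continue
                bad = set(gt) - locus.alleles
                if bad:
                    raise ValidationError(
                        f"family {fam.family_id} {role} at {rsid}: allele(s) "
                        f"{sorted(bad)} not in {{{locus.major},{locus.minor}}}"
                    )

    def locus(self, rsid: str) -> Locus:
        try:
            return self._by_rsid[rsid]
        except KeyError:
            raise ValidationError(f"locus {rsid} not declared in cohort") from None

    @property
    def rsids(self) -> list[str]:
        return [locus.rsid for locus in self.loci]

    def families_with_status(self, status: str) -> Iterator[Family]:
        if status not in STATUSES:
            raise ValidationError(f"status must be one of {STATUSES}, got {status!r}")
        return (f for f in self.families if f.status == status)

    def n_families(self, status: str | None = None) -> int:
        if status is None:
            return len(self.families)
        return sum(1 for _ in self.families_with_status(status))


def trio_consistent(mother: tuple[str, str], father: tuple[str, str],
                    child: tuple[str, str]) -> bool:
    """Can the child's alleles be split into one maternal + one paternal copy?"""
    child_c = genotype(*child)
    return any(
        genotype(m, f) == child_c for m in mother for f in father
    )


def dyad_consistent(mother: tuple[str, str], child: tuple[str, str]) -> bool:
    """Dyad check: the child must share at least one allele with the mother."""
    return bool(set(mother) & set(child))


def check_mendelian(cohort: Cohort) -> list[MendelViolation]:
    """Scan every family x locus for Mendelian inconsistencies.

    A violation is reported iff no assignment of one maternal and one
    paternal allele reproduces the offspring genotype (for dyads: the
    offspring shares no allele with the mother).  Loci with any missing
    genotype in the family are skipped.
    """
    violations: list[MendelViolation] = []
    for fam in cohort.families:
        for locus in cohort.loci:
            rsid = locus.rsid
            m = fam.mother.get(rsid)
            c = fam.offspring.get(rsid)
            if m is None or c is None:
                continue
            if fam.father is None:
                if not dyad_consistent(m, c):
                    violations.append(MendelViolation(
                        fam.family_id, rsid,
                        f"dyad: offspring {''.join(c)} shares no allele with "
                        f"mother {''.join(m)}"))
                continue
            f = fam.father.get(rsid)
            if f is None:
                if not dyad_consistent(m, c):
                    violations.append(MendelViolation(
                        fam.family_id, rsid,
                        f"offspring {''.join(c)} shares no allele with mother "
                        f"{''.join(m)} (father untyped)"))
                continue
            if not trio_consistent(m, f, c):
                violations.append(MendelViolation(
                    fam.family_id, rsid,
                    f"offspring {''.join(c)} impossible from mother "
                    f"{''.join(m)} x father {''.join(f)}"))
    return violations
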