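import itertools

import pytest

from triadtest import Cohort, Family, Locus, genotype


@pytest.fixture
def ga_locus() -> Locus:
    return Locus("rs9380142", "HLA-G", "G", "A")


@pytest.fixture
def cg_locus() -> Locus:
    return Locus("rs1063320", "HLA-G", "C", "G")


def make_family(fid, locus, mother, father, child, status="control"):
    """Build a one-locus family from allele strings like 'GA' (or None)."""
    def gt(s):
        return None if s is None else genotype(s[0], s[1])
    return Family(
        family_id=fid, status=status,
        mother={locus.rsid: gt(mother)},
        offspring={locus.rsid: gt(child)},
        father=None if father is None else {locus.rsid: gt(father)},
    )


def single_locus_cohort(locus, triads):
    """triads: iterable of (mother, father, child, status) allele strings."""
    fams = [make_family(f"f{i}", locus, m, f, c, status)
            for i, (m, f, c, status) in enumerate(triads)]
    return Cohort(loci=[locus], families=fams)


def cohort_from_genotype_counts(locus, role, case_counts, control_counts):
    """Cohort whose `role` members realise exact (AA, AB, BB) genotype counts.

    Only the requested role is genotyped, so per-locus complete-case
    filtering leaves exactly these counts for that role.
    """
    aa = genotype(locus.major, locus.major)
    ab = genotype(locus.major, locus.minor)
    bb = genotype(locus.minor, locus.minor)
    families = []
    counter = itertools.count()
    for status, counts in (("case", case_counts), ("control", control_counts)):
        for gt, n in zip((aa, ab, bb), counts):
            for _ in range(n):
                i = next(counter)
                member = {locus.rsid: gt}
                empty = {locus.rsid: None}
                families.append(Family(
                    family_id=f"{status}{i}", status=status,
                    mother=member if role == "mother" else empty,
                    offspring=member if role == "offspring" else empty,
                    father=member if role == "father" else None,
                ))
    return Cohort(loci=[locus], families=families)
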