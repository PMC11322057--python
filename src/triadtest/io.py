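"""Readers and writers for linkage/PED pedigree files and small TSV inputs.

The PED dialect accepted here is the classic 6-column linkage layout::

    family_id individual_id father_id mother_id sex phenotype  a1 a2  [a1 a2 ...]

with two allele columns per locus, whitespace- (tab or space) separated.
Allele coding may be letters (A/C/G/T) or numeric 1/2 (1 = major allele,
2 = minor allele of the locus definition); ``0`` marks a missing allele.
Phenotype coding follows the linkage convention: 1 = control (unaffected),
2 = case (affected), 0 or -9 = missing.

Families are assembled from the parent-ID columns: any individual whose
mother-ID points at another row in the file is treated as the offspring of a
family; its linked mother must be present, its father may be absent (dyad).
Family case/control status is taken from the *offspring* row's phenotype.
Rows that are linked to no offspring are ignored with a logged warning.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .cohort import Cohort, Family, Genotype, Locus, genotype
from .errors import PedFormatError, ValidationError

logger = logging.getLogger(__name__)

MISSING_ALLELE = "0"
MISSING_PHENOTYPES = {"0", "-9"}


def read_loci(path: str | Path) -> list[Locus]:
    """Read a locus-definition TSV with header columns rsid, gene, major, minor."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"rsid", "gene", "major", "minor"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: locus file must have columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    return [
        Locus(row.rsid, row.gene, row.major, row.minor)
        for row in df.itertuples(index=False)
    ]


def _decode_allele(symbol: str, locus: Locus, line_no: int) -> str | None:
    if symbol == MISSING_ALLELE:
        return None
    if symbol == "1":
        return locus.major
    if symbol == "2":
        return locus.minor
    if symbol in locus.alleles:
        return symbol
    raise ValidationError(
        f"line {line_no}: allele {symbol!r} is not valid for locus "
        f"{locus.rsid} ({locus.major}/{locus.minor})"
    )


def _decode_genotypes(fields: list[str], loci: list[Locus],
                      line_no: int) -> dict[str, Genotype]:
    genos: dict[str, Genotype] = {}
    for i, locus in enumerate(loci):
        a1 = _decode_allele(fields[6 + 2 * i], locus, line_no)
        a2 = _decode_allele(fields[7 + 2 * i], locus, line_no)
        # half-called genotypes are treated as missing, as in most PED tools
        genos[locus.rsid] = None if (a1 is None or a2 is None) else genotype(a1, a2)
    return genos


def read_ped(path: str | Path, loci: list[Locus]) -> Cohort:
    """Parse a PED file into a :class:`Cohort` of mother-(father)-offspring units."""
    n_expected = 6 + 2 * len(loci)
    rows: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != n_expected:
                raise PedFormatError(
                    f"expected {n_expected} columns "
                    f"(6 + 2 x {len(loci)} loci), got {len(fields)}",
                    line=line_no,
                )
            fid, iid, father_id, mother_id, _sex, phen = fields[:6]
            if iid in rows:
                raise ValidationError(f"line {line_no}: duplicate individual ID {iid!r}")
            rows[iid] = {
                "fid": fid,
                "father_id": father_id,
                "mother_id": mother_id,
                "phen": phen,
                "genotypes": _decode_genotypes(fields, loci, line_no),
            }
            order.append(iid)

    families: list[Family] = []
    used: set[str] = set()
    for iid in order:
        row = rows[iid]
        father_id, mother_id = row["father_id"], row["mother_id"]
        if father_id == "0" and mother_id == "0":
            continue  # founder row; picked up via its offspring
        if mother_id == "0" or mother_id not in rows:
            raise ValidationError(
                f"offspring {iid}: mother {mother_id!r} not present in file "
                "(mother is required for every family)"
            )
        phen = row["phen"]
        if phen in MISSING_PHENOTYPES:
            logger.warning(
                "family %s: offspring %s has missing phenotype (%s); excluded",
                row["fid"], iid, phen)
            used.update({iid, mother_id})
            if father_id in rows:
                used.add(father_id)
            continue
        if phen == "2":
            status = "case"
        elif phen == "1":
            status = "control"
        else:
            raise PedFormatError(
                f"offspring {iid}: phenotype must be 1 (control), 2 (case) or "
                f"0/-9 (missing), got {phen!r}")
        father_genos = None
        if father_id != "0":
            if father_id in rows:
                father_genos = rows[father_id]["genotypes"]
            else:
                logger.warning(
                    "family %s: father %s referenced but not in file; "
                    "treated as dyad", row["fid"], father_id)
        families.append(Family(
            family_id=row["fid"],
            status=status,
            mother=rows[mother_id]["genotypes"],
            offspring=row["genotypes"],
            father=father_genos,
        ))
        used.update({iid, mother_id})
        if father_id in rows:
            used.add(father_id)

    for iid in order:
        if iid not in used and rows[iid]["mother_id"] == "0":
            logger.warning("individual %s is linked to no family; ignored", iid)
    return Cohort(loci=list(loci), families=families)


def _encode_genotype(gt: Genotype) -> tuple[str, str]:
    return ("0", "0") if gt is None else gt


def write_ped(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort back to PED (letter alleles, tab-separated).

    Member IDs are synthesised as <family_id>_M / _F / _C; parents carry a
    missing phenotype, the offspring row carries the family status.
    """
    rsids = cohort.rsids
    with open(path, "w") as fh:
        for fam in cohort.families:
            mid, fid_, cid = (f"{fam.family_id}_{x}" for x in ("M", "F", "C"))
            phen = "2" if fam.status == "case" else "1"
            rows = [(mid, "0", "0", "2", "0", fam.mother)]
            father_id = "0"
            if fam.father is not None:
                rows.append((fid_, "0", "0", "1", "0", fam.father))
                father_id = fid_
            rows.append((cid, father_id, mid, "0", phen, fam.offspring))
            for iid, f_id, m_id, sex, ph, genos in rows:
                alleles: list[str] = []
                for rsid in rsids:
                    alleles.extend(_encode_genotype(genos.get(rsid)))
                fh.write("\t".join(
                    [fam.family_id, iid, f_id, m_id, sex, ph] + alleles) + "\n")


def read_count_table(path: str | Path) -> "pd.DataFrame":
    """Read a tidy ``group<TAB>category<TAB>count`` TSV into a groups x
    categories integer pivot (for table-driven analyses)."""
    df = pd.read_csv(path, sep="\t", dtype={"group": str, "category": str})
    required = {"group", "category", "count"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: count table must have columns {sorted(required)}")
    pivot = df.pivot(index="group", columns="category", values="count")
    if pivot.isna().any().any():
        raise ValidationError(f"{path}: missing group x category combinations")
    return pivot.astype(int)
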