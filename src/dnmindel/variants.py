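"""Candidate indel representation, allele normalization and trio file IO.

Candidates follow VCF convention: 1-based anchor position, ref and alt
alleles sharing their first base.  All candidates are normalized on ingest
(left-aligned and parsimonious) so that site identity — the key used for
deduplication, truth matching and training-set assembly — is representation
independent.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import pysam

__all__ = [
    "CandidateIndel",
    "normalize_indel",
    "Pedigree",
    "read_pedigree",
    "read_candidates_vcf",
    "read_candidates_tsv",
    "read_trio_genotypes",
    "ROLES",
]

ROLES = ("father", "mother", "offspring")


@dataclass(frozen=True, order=True)
class CandidateIndel:
    """One putative de novo indel site in VCF convention."""

    chrom: str
    pos: int  # 1-based anchor
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        if not self.ref_allele or not self.alt_allele:
            raise ValueError(f"empty allele at {self.chrom}:{self.pos}")
        if self.ref_allele[0] != self.alt_allele[0]:
            raise ValueError(
                f"ref/alt must share their first base (VCF convention) at "
                f"{self.chrom}:{self.pos} {self.ref_allele}>{self.alt_allele}"
            )
        if len(self.ref_allele) == len(self.alt_allele):
            raise ValueError(
                f"not an indel at {self.chrom}:{self.pos}: "
                f"{self.ref_allele}>{self.alt_allele}"
            )

    @property
    def indel_type(self) -> str:
        return "insertion" if len(self.alt_allele) > len(self.ref_allele) else "deletion"

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref_allele) - len(self.alt_allele))

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


def normalize_indel(
    chrom: str, pos: int, ref: str, alt: str, reference: Mapping[str, str]
) -> CandidateIndel:
    """Left-align and make parsimonious one biallelic indel.

    Standard variant normalization: repeatedly trim a shared last base
    (extending left with the reference base when an allele would empty),
    then trim the shared prefix keeping one anchor base.
    """
    ref, alt = ref.upper(), alt.upper()
    seq = reference[chrom]
    while True:
        if len(ref) > 0 and len(alt) > 0 and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if len(ref) == 0 or len(alt) == 0:
                if pos == 1:
                    raise ValueError(f"cannot left-extend at {chrom}:{pos}")
                pos -= 1
                base = str(seq[pos - 1 : pos]).upper()
                ref, alt = base + ref, base + alt
        else:
            break
    # trim shared prefix, keep one anchor base
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0] and ref[1] == alt[1]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return CandidateIndel(chrom, pos, ref, alt)


@dataclass
class Pedigree:
    """father/mother/offspring sample names of one trio."""

    father: str
    mother: str
    offspring: str
    family: str = "FAM"

    def role_of(self, sample: str) -> Optional[str]:
        for role in ROLES:
            if getattr(self, role) == sample:
                return role
        return None


def read_pedigree(path: str) -> Pedigree:
    """Parse a 6-column PED file; the offspring is the individual whose
    father and mother columns are both non-zero."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"PED line has {len(parts)} < 6 columns: {line!r}")
            rows.append(parts)
    children = [r for r in rows if r[2] != "0" and r[3] != "0"]
    if len(children) != 1:
        raise ValueError(
            f"pedigree must contain exactly one offspring with both parents, found {len(children)}"
        )
    child = children[0]
    ids = {r[1] for r in rows}
    for parent, label in ((child[2], "father"), (child[3], "mother")):
        if parent not in ids:
            raise ValueError(f"{label} {parent!r} of {child[1]!r} not in pedigree")
    return Pedigree(father=child[2], mother=child[3], offspring=child[1], family=child[0])


def _norm_or_none(chrom, pos, ref, alt, reference):
    if reference is None:
        try:
            return CandidateIndel(chrom, pos, ref.upper(), alt.upper())
        except ValueError:
            return None
    try:
        return normalize_indel(chrom, pos, ref, alt, reference)
    except ValueError:
        return None


def read_candidates_vcf(
    path: str, reference: Optional[Mapping[str, str]] = None
) -> List[CandidateIndel]:
    """Read biallelic indel records from a VCF; SNVs and multi-allelic
    records are skipped. Normalizes when a reference is supplied."""
    out: List[CandidateIndel] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if alt is None or not alt.isalpha() or len(ref) == len(alt):
                continue
            cand = _norm_or_none(rec.chrom, rec.pos, ref, alt, reference)
            if cand is not None:
                out.append(cand)
    return out


def read_candidates_tsv(
    path: str, reference: Optional[Mapping[str, str]] = None
) -> List[CandidateIndel]:
    """Read candidates from a site TSV with columns chrom, pos, ref, alt
    (header optional)."""
    out = []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "chrom":
                continue
            chrom, pos, ref, alt = row[0], int(row[1]), row[2], row[3]
            cand = _norm_or_none(chrom, pos, ref, alt, reference)
            if cand is not None:
                out.append(cand)
    return out


def read_trio_genotypes(
    path: str,
    pedigree: Pedigree,
    reference: Optional[Mapping[str, str]] = None,
) -> List[Dict]:
    """Read a jointly-called trio VCF into per-site genotype records.

    Returns a list of dicts with keys ``site`` (normalized
    :class:`CandidateIndel`) and ``father``/``mother``/``offspring`` genotype
    tuples (e.g. ``(0, 1)``).  Multi-allelic records, SNVs and sites with
    missing or half-called genotypes are excluded.
    """
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = set(vcf.header.samples)
        for role in ROLES:
            name = getattr(pedigree, role)
            if name not in samples:
                raise ValueError(f"pedigree member {name!r} ({role}) absent from {path}")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if alt is None or not alt.isalpha() or len(ref) == len(alt):
                continue
            gts = {}
            ok = True
            for role in ROLES:
                gt = rec.samples[getattr(pedigree, role)].get("GT")
                if gt is None or len(gt) != 2 or any(a is None for a in gt):
                    ok = False
                    break
                gts[role] = tuple(sorted(gt))
            if not ok:
                continue
            cand = _norm_or_none(rec.chrom, rec.pos, ref, alt, reference)
            if cand is None:
                continue
            out.append({"site": cand, **gts})
    return out
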