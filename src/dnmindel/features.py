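"""Pileup feature extraction for candidate indels in a trio.

For each candidate site the extractor computes ten pileup metrics per family
member — depth, indel-allele support and balance, mapping and base quality,
strand balance, soft-clipping, local mismatch noise and other indel alleles
at the site — and appends seven site-level features: indel length and type
plus the homopolymer/STR repeat context of the reference.  The resulting
37-value vector has a fixed, fingerprinted order shared between training
and prediction.

A read counts as supporting the candidate allele only when its alignment
contains an insertion or deletion of the same type and length whose
left-aligned reference position matches the candidate's; any other indel
observed near the site counts toward ``other_indel_count`` instead.
Duplicate, secondary and supplementary reads, and reads below the mapping
quality threshold, are excluded from all metrics.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, fields
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .reads import D, I, M, Read, ReadSet, S
from .repeats import DEFAULT_FLANK, RepeatAnnotation, annotate_site
from .variants import ROLES, CandidateIndel

__all__ = [
    "SampleSiteMetrics",
    "TrioFeatureVector",
    "FEATURE_NAMES",
    "METRIC_NAMES",
    "schema_fingerprint",
    "count_allele_support",
    "compute_sample_metrics",
    "extract_trio_features",
]

DEFAULT_MIN_MAPQ = 20
MISMATCH_THRESHOLD = 3  # reads with more non-indel mismatches count as noisy
OTHER_INDEL_WINDOW = 10  # bp around the anchor in which foreign indels are tallied
FLANK_BASES = 5  # read bases per side for the flanking base-quality mean


@dataclass(frozen=True)
class SampleSiteMetrics:
    """Pileup metrics for one family member at one candidate site."""

    depth: int
    alt_count: int
    alt_fraction: float
    mean_mapq_all: float
    mean_mapq_alt: float
    mean_baseq_flank: float
    softclip_fraction: float
    fwd_alt_fraction: float
    mismatch_fraction: float
    other_indel_count: int

    def __post_init__(self):
        if not (0 <= self.alt_count <= self.depth):
            raise ValueError(f"alt_count {self.alt_count} outside [0, depth={self.depth}]")
        for name in ("alt_fraction", "softclip_fraction", "fwd_alt_fraction", "mismatch_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0,1]")


METRIC_NAMES: Tuple[str, ...] = tuple(f.name for f in fields(SampleSiteMetrics))

SITE_FEATURE_NAMES: Tuple[str, ...] = (
    "indel_length",
    "indel_type_code",
    "is_homopolymer",
    "homopolymer_tract_length",
    "is_str",
    "str_unit_size",
    "str_copy_count",
)

FEATURE_NAMES: Tuple[str, ...] = tuple(
    f"{role}_{m}" for role in ROLES for m in METRIC_NAMES
) + SITE_FEATURE_NAMES


def schema_fingerprint(names: Sequence[str] = FEATURE_NAMES) -> str:
    """Stable fingerprint of the feature-name order, checked at prediction
    time so a model is never applied to a differently-laid-out vector."""
    return hashlib.sha256("\n".join(names).encode()).hexdigest()[:16]


EMPTY_PILEUP_METRICS = SampleSiteMetrics(
    depth=0,
    alt_count=0,
    alt_fraction=0.0,
    mean_mapq_all=0.0,
    mean_mapq_alt=0.0,
    mean_baseq_flank=0.0,
    softclip_fraction=0.0,
    fwd_alt_fraction=0.5,
    mismatch_fraction=0.0,
    other_indel_count=0,
)


@dataclass(frozen=True)
class TrioFeatureVector:
    """Fixed-order numeric features for one candidate site."""

    site: CandidateIndel
    values: Dict[str, float]

    def __post_init__(self):
        if tuple(self.values) != FEATURE_NAMES:
            raise ValueError("feature vector does not match the published schema order")

    def as_row(self) -> List[float]:
        return [self.values[k] for k in FEATURE_NAMES]


def left_align_event(
    etype: str, ref_pos: int, length: int, inserted: str, chrom_seq
) -> int:
    """Left-align one read indel event against the reference; returns the
    0-based leftmost event position (first deleted base, or insertion point)."""
    if etype == "D":
        p = ref_pos
        while p > 0 and str(chrom_seq[p - 1 : p]).upper() == str(
            chrom_seq[p + length - 1 : p + length]
        ).upper():
            p -= 1
        return p
    p = ref_pos
    s = inserted.upper()
    while p > 0 and str(chrom_seq[p - 1 : p]).upper() == s[-1]:
        s = str(chrom_seq[p - 1 : p]).upper() + s[:-1]
        p -= 1
    return p


def candidate_event(site: CandidateIndel) -> Tuple[str, int, int]:
    """The (type, 0-based leftmost position, length) of a normalized
    candidate: deletions start at the base after the anchor; insertions are
    placed after the anchor."""
    if site.indel_type == "deletion":
        return ("D", site.pos, site.indel_length)  # pos is 1-based anchor -> 0-based pos+1-1
    return ("I", site.pos, site.indel_length)


def _usable(read: Read, min_mapq: int) -> bool:
    return (
        read.mapq >= min_mapq
        and not read.is_duplicate
        and not read.is_secondary
        and not read.is_supplementary
    )


def _overlapping(reads: Sequence[Read], site: CandidateIndel, min_mapq: int) -> List[Read]:
    p0 = site.pos - 1  # 0-based anchor
    out = []
    for r in reads:
        if r.chrom != site.chrom:
            raise ValueError(
                f"read {r.name} on {r.chrom} does not match site chromosome {site.chrom}"
            )
        if _usable(r, min_mapq) and r.pos <= p0 < r.reference_end:
            out.append(r)
    return out


def _read_supports_alt(read: Read, event: Tuple[str, int, int], chrom_seq) -> bool:
    etype, epos, elen = event
    for rtype, rpos, rlen, rins in read.indel_events():
        if rtype == etype and rlen == elen:
            if left_align_event(rtype, rpos, rlen, rins, chrom_seq) == epos:
                return True
    return False


def count_allele_support(
    reads: Sequence[Read],
    site: CandidateIndel,
    chrom_seq,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> Tuple[int, int]:
    """(depth, alt_count) at the candidate site after pileup filtering."""
    overlapping = _overlapping(reads, site, min_mapq)
    event = candidate_event(site)
    alt = sum(1 for r in overlapping if _read_supports_alt(r, event, chrom_seq))
    return len(overlapping), alt


def _mismatches(read: Read, chrom_seq) -> int:
    """Non-indel mismatches of a read against the reference (CIGAR walk)."""
    n = 0
    r, q = read.pos, 0
    for op, ln in read.cigar:
        if op == M:
            ref_block = str(chrom_seq[r : r + ln]).upper()
            qry_block = read.seq[q : q + ln].upper()
            n += sum(1 for a, b in zip(ref_block, qry_block) if a != b)
            r += ln
            q += ln
        elif op == D:
            r += ln
        elif op in (I, S):
            q += ln
    return n


def compute_sample_metrics(
    reads: Sequence[Read],
    site: CandidateIndel,
    chrom_seq,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> SampleSiteMetrics:
    """All ten pileup metrics for one sample at one site.

    Degenerate pileups take fixed documented defaults: an empty pileup
    yields all-zero means and fractions with ``fwd_alt_fraction = 0.5``;
    ``alt_count = 0`` yields ``mean_mapq_alt = 0`` and
    ``fwd_alt_fraction = 0.5``.
    """
    overlapping = _overlapping(reads, site, min_mapq)
    if not overlapping:
        return EMPTY_PILEUP_METRICS
    # determinism regardless of input order
    overlapping.sort(key=lambda r: (r.pos, r.name))
    event = candidate_event(site)
    p0 = site.pos - 1

    alt_reads = [r for r in overlapping if _read_supports_alt(r, event, chrom_seq)]
    depth, alt_count = len(overlapping), len(alt_reads)

    flank_quals: List[int] = []
    for r in overlapping:
        q = r.query_offset_at(p0)
        if q is None:
            continue
        flank_quals.extend(r.quals[max(0, q - FLANK_BASES) : q])
        flank_quals.extend(r.quals[q + 1 : q + 1 + FLANK_BASES])

    other_alleles = set()
    for r in overlapping:
        for rtype, rpos, rlen, rins in r.indel_events():
            la = left_align_event(rtype, rpos, rlen, rins, chrom_seq)
            if abs(la - p0) <= OTHER_INDEL_WINDOW and (rtype, la, rlen) != event:
                other_alleles.add((rtype, la, rlen))

    n_mismatchy = sum(1 for r in overlapping if _mismatches(r, chrom_seq) > MISMATCH_THRESHOLD)
    n_softclip = sum(1 for r in overlapping if any(op == S for op, _ in r.cigar))

    return SampleSiteMetrics(
        depth=depth,
        alt_count=alt_count,
        alt_fraction=alt_count / depth,
        mean_mapq_all=sum(r.mapq for r in overlapping) / depth,
        mean_mapq_alt=(sum(r.mapq for r in alt_reads) / alt_count) if alt_count else 0.0,
        mean_baseq_flank=(sum(flank_quals) / len(flank_quals)) if flank_quals else 0.0,
        softclip_fraction=n_softclip / depth,
        fwd_alt_fraction=(
            sum(1 for r in alt_reads if not r.is_reverse) / alt_count if alt_count else 0.5
        ),
        mismatch_fraction=n_mismatchy / depth,
        other_indel_count=len(other_alleles),
    )


def extract_trio_features(
    trio_alignments: Mapping[str, ReadSet],
    site: CandidateIndel,
    reference: Mapping[str, str],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    flank: int = DEFAULT_FLANK,
    annotation: Optional[RepeatAnnotation] = None,
) -> TrioFeatureVector:
    """Assemble the full 37-feature vector for one candidate site.

    ``trio_alignments`` maps the roles ``father``/``mother``/``offspring``
    to their :class:`ReadSet`.  ``annotation`` may be supplied to reuse a
    precomputed repeat annotation; otherwise the reference is annotated here.
    """
    for role in ROLES:
        if role not in trio_alignments:
            raise ValueError(f"alignment source missing for pedigree role {role!r}")
    chrom_seq = reference[site.chrom]
    if annotation is None:
        annotation = annotate_site(reference, site.chrom, site.pos, flank=flank)

    values: Dict[str, float] = {}
    p0 = site.pos - 1
    span = max(site.indel_length, 1)
    for role in ROLES:
        pile = trio_alignments[role].fetch(site.chrom, p0, p0 + 1 + span)
        metrics = compute_sample_metrics(pile, site, chrom_seq, min_mapq=min_mapq)
        for m in METRIC_NAMES:
            values[f"{role}_{m}"] = float(getattr(metrics, m))
    values["indel_length"] = float(site.indel_length)
    values["indel_type_code"] = 1.0 if site.indel_type == "insertion" else 0.0
    values["is_homopolymer"] = float(annotation.is_homopolymer)
    values["homopolymer_tract_length"] = float(annotation.homopolymer_tract_length)
    values["is_str"] = float(annotation.is_str)
    values["str_unit_size"] = float(annotation.str_unit_size)
    values["str_copy_count"] = float(annotation.str_copy_count)
    return TrioFeatureVector(site=site, values=values)
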