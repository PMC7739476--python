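"""Synthetic de novo indels by parent/offspring alignment exchange.

True, experimentally validated de novo indels are far too scarce to train a
classifier on.  The filter therefore manufactures positives: at sites where
one parent is heterozygous for an indel while the other parent and the
offspring are homozygous reference, the reads of the carrier parent and the
offspring are exchanged.  After the exchange the offspring's pileup carries
the het-indel evidence and neither parent's does — exactly the signature of
a real de novo indel — while every read keeps its authentic sequencing
noise, making the site a realistic labeled positive.

The module also assembles the false-de-novo candidate pool: putative calls
from upstream de novo callers minus the validated ones (the random sampling
down to the requested count happens during training-set assembly).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

from .reads import Read, ReadSet
from .variants import CandidateIndel

__all__ = [
    "SwapSite",
    "SwappedTrio",
    "find_swap_sites",
    "swap_alignments",
    "build_false_dnm_pool",
    "DEFAULT_SWAP_WINDOW",
]

logger = logging.getLogger(__name__)

DEFAULT_SWAP_WINDOW = 500  # bp either side of the anchor


@dataclass(frozen=True)
class SwapSite:
    """One site eligible for the alignment exchange."""

    site: CandidateIndel
    donor_parent: str  # "father" or "mother" (the het-indel carrier)
    region_start: int  # 0-based half-open swap window
    region_end: int

    def __post_init__(self):
        if self.donor_parent not in ("father", "mother"):
            raise ValueError(f"donor parent must be father or mother, got {self.donor_parent!r}")
        if not (self.region_start <= self.site.pos - 1 < self.region_end):
            raise ValueError("swap window must contain the site anchor")


@dataclass
class SwappedTrio:
    """Read sets after one exchange, plus the provenance swap site."""

    reads: Dict[str, ReadSet]
    swap: SwapSite
    n_moved_donor_to_offspring: int
    n_moved_offspring_to_donor: int


HET = (0, 1)
HOMREF = (0, 0)


def find_swap_sites(
    trio_genotypes: Sequence[dict],
    indel_sites: Iterable[CandidateIndel] = None,
    window: int = DEFAULT_SWAP_WINDOW,
) -> List[SwapSite]:
    """Select exchange-eligible sites from a per-site trio genotype table.

    A site qualifies when exactly one parent is heterozygous for the indel
    and both the other parent and the offspring are homozygous reference.
    ``trio_genotypes`` is a sequence of records with keys ``site`` (a
    :class:`CandidateIndel`) and ``father``/``mother``/``offspring``
    genotype tuples (as produced by
    :func:`dnmindel.variants.read_trio_genotypes`); records with missing or
    half-called genotypes must already be excluded there.  ``indel_sites``
    optionally restricts the search to a site subset.  Output is in genomic
    order.
    """
    allowed = {c.key for c in indel_sites} if indel_sites is not None else None
    out: List[SwapSite] = []
    for rec in trio_genotypes:
        for member in ("father", "mother", "offspring"):
            if member not in rec:
                raise ValueError(f"genotype table record missing member {member!r}")
        site: CandidateIndel = rec["site"]
        if allowed is not None and site.key not in allowed:
            continue
        if rec["offspring"] != HOMREF:
            continue
        f, m = rec["father"], rec["mother"]
        if f == HET and m == HOMREF:
            donor = "father"
        elif m == HET and f == HOMREF:
            donor = "mother"
        else:
            continue
        anchor0 = site.pos - 1
        out.append(
            SwapSite(
                site=site,
                donor_parent=donor,
                region_start=max(0, anchor0 - window),
                region_end=anchor0 + window + site.indel_length,
            )
        )
    out.sort(key=lambda s: (s.site.chrom, s.site.pos))
    return out


def swap_alignments(
    donor_reads: ReadSet, offspring_reads: ReadSet, swap: SwapSite
) -> SwappedTrio:
    """Exchange all reads overlapping the swap window between the donor
    parent and the offspring, in place.

    Moved reads have their sample label rewritten to the recipient.  The
    combined read multiset of the two members is conserved, and applying the
    same swap twice restores the original membership.  An empty donor window
    is signalled with a warning and no exchange (the caller drops the site
    from the synthetic pool).
    """
    chrom = swap.site.chrom
    from_donor = donor_reads.fetch(chrom, swap.region_start, swap.region_end)
    from_child = offspring_reads.fetch(chrom, swap.region_start, swap.region_end)
    result = SwappedTrio(
        reads={"donor": donor_reads, "offspring": offspring_reads},
        swap=swap,
        n_moved_donor_to_offspring=len(from_donor),
        n_moved_offspring_to_donor=len(from_child),
    )
    if not from_donor:
        logger.warning(
            "no donor reads over swap window %s:%d-%d; site dropped",
            chrom, swap.region_start, swap.region_end,
        )
        result.n_moved_offspring_to_donor = 0
        return result
    donor_reads.remove(from_donor)
    offspring_reads.remove(from_child)
    for r in from_donor:
        r.sample = offspring_reads.sample
    for r in from_child:
        r.sample = donor_reads.sample
    offspring_reads.add(from_donor)
    donor_reads.add(from_child)
    return result


def apply_swaps(
    reads: Dict[str, ReadSet], swaps: Sequence[SwapSite]
) -> List[SwapSite]:
    """Apply a list of exchanges greedily in genomic order, skipping any
    site whose window intersects an already-swapped window (prevents
    double-moving reads) or whose donor window is empty.  Returns the sites
    actually swapped."""
    done: List[SwapSite] = []
    applied: List[Tuple[str, int, int]] = []
    for swap in sorted(swaps, key=lambda s: (s.site.chrom, s.site.pos)):
        clash = any(
            c == swap.site.chrom and swap.region_start < e and s < swap.region_end
            for c, s, e in applied
        )
        if clash:
            logger.info("skipping swap at %s:%d: window overlaps an earlier swap",
                        swap.site.chrom, swap.site.pos)
            continue
        result = swap_alignments(reads[swap.donor_parent], reads["offspring"], swap)
        if result.n_moved_donor_to_offspring:
            done.append(swap)
            applied.append((swap.site.chrom, swap.region_start, swap.region_end))
    return done


def build_false_dnm_pool(
    putative_calls: Iterable[CandidateIndel],
    validated: Iterable[CandidateIndel],
) -> List[CandidateIndel]:
    """Putative de novo calls minus the validated ones.

    Site identity is the normalized (chrom, pos, ref, alt) key, so
    representation variants of a validated site are still excluded as long
    as both inputs were normalized on ingest.  Order is genomic; duplicates
    collapse.
    """
    validated_keys: Set = {v.key for v in validated}
    seen: Set = set()
    out: List[CandidateIndel] = []
    for c in putative_calls:
        if c.key in validated_keys or c.key in seen:
            continue
        seen.add(c.key)
        out.append(c)
    out.sort()
    return out
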