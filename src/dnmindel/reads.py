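"""Lightweight aligned-read container shared by the simulator, the
read-swap synthesizer and the feature extractor.

Reads are held in plain Python objects rather than htslib records so that
simulated trios can be swapped and piled up in memory without round-tripping
through BAM; converters to and from :mod:`pysam` provide the on-disk
interface (coordinate-sorted, indexed BAM, or SAM text for tests).
"""

from __future__ import annotations

import bisect
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple

import pysam

# CIGAR ops we emit/consume. Ops are (code, length) with codes from the SAM
# spec: 0=M 1=I 2=D 4=S (we treat 7/8 as M on ingest).
M, I, D, S = 0, 1, 2, 4
_CONSUMES_REF = {M: True, I: False, D: True, S: False}
_CONSUMES_QUERY = {M: True, I: True, D: False, S: True}


class Read:
    """One aligned read: coordinates, CIGAR, sequence, qualities, flags."""

    __slots__ = (
        "name",
        "chrom",
        "pos",
        "mapq",
        "cigar",
        "seq",
        "quals",
        "is_reverse",
        "is_duplicate",
        "is_secondary",
        "is_supplementary",
        "sample",
    )

    def __init__(
        self,
        name: str,
        chrom: str,
        pos: int,
        mapq: int,
        cigar: Tuple[Tuple[int, int], ...],
        seq: str,
        quals: bytes,
        is_reverse: bool = False,
        is_duplicate: bool = False,
        is_secondary: bool = False,
        is_supplementary: bool = False,
        sample: str = "",
    ):
        self.name = name
        self.chrom = chrom
        self.pos = pos  # 0-based leftmost reference position
        self.mapq = mapq
        self.cigar = tuple(cigar)
        self.seq = seq
        self.quals = quals
        self.is_reverse = is_reverse
        self.is_duplicate = is_duplicate
        self.is_secondary = is_secondary
        self.is_supplementary = is_supplementary
        self.sample = sample

    @property
    def reference_end(self) -> int:
        """0-based exclusive rightmost reference position."""
        return self.pos + sum(ln for op, ln in self.cigar if _CONSUMES_REF[op])

    def query_offset_at(self, ref_pos: int) -> Optional[int]:
        """Query offset of the base aligned at ``ref_pos`` (0-based), or the
        last query base before it when ``ref_pos`` falls in a deletion;
        ``None`` when the read does not cover the position."""
        if not (self.pos <= ref_pos < self.reference_end):
            return None
        r, q = self.pos, 0
        last_q = None
        for op, ln in self.cigar:
            if op == M:
                if r <= ref_pos < r + ln:
                    return q + (ref_pos - r)
                r += ln
                q += ln
                last_q = q - 1
            elif op == D:
                if r <= ref_pos < r + ln:
                    return last_q
                r += ln
            elif _CONSUMES_QUERY[op]:
                q += ln
        return None

    def indel_events(self) -> List[Tuple[str, int, int, str]]:
        """Indel operations as (type, ref_pos, length, inserted_seq) with
        ``ref_pos`` the 0-based first deleted base (deletions) or the
        insertion point (insertions, bases inserted before ``ref_pos``)."""
        events = []
        r, q = self.pos, 0
        for op, ln in self.cigar:
            if op == I:
                events.append(("I", r, ln, self.seq[q : q + ln]))
                q += ln
            elif op == D:
                events.append(("D", r, ln, ""))
                r += ln
            else:
                if _CONSUMES_REF[op]:
                    r += ln
                if _CONSUMES_QUERY[op]:
                    q += ln
        return events

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Read({self.name} {self.chrom}:{self.pos} {self.cigar})"


class ReadSet:
    """Position-indexed collection of reads for one sample, supporting
    region fetches over in-memory reads (mirrors ``AlignmentFile.fetch``)."""

    def __init__(self, reads: Iterable[Read] = (), sample: str = ""):
        self.sample = sample
        self._reads: List[Read] = sorted(reads, key=lambda r: (r.chrom, r.pos))
        self._rebuild_index()

    def _rebuild_index(self) -> None:
        self._starts = [(r.chrom, r.pos) for r in self._reads]
        self._max_span = max(
            (r.reference_end - r.pos for r in self._reads), default=0
        )

    def __len__(self) -> int:
        return len(self._reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self._reads)

    def fetch(self, chrom: str, start: int, end: int) -> List[Read]:
        """All reads overlapping [start, end) on ``chrom`` (0-based)."""
        lo = bisect.bisect_left(self._starts, (chrom, start - self._max_span))
        hi = bisect.bisect_left(self._starts, (chrom, end))
        return [
            r
            for r in self._reads[lo:hi]
            if r.pos < end and r.reference_end > start
        ]

    def add(self, reads: Iterable[Read]) -> None:
        self._reads.extend(reads)
        self._reads.sort(key=lambda r: (r.chrom, r.pos))
        self._rebuild_index()

    def remove(self, reads: Sequence[Read]) -> None:
        drop = {id(r) for r in reads}
        self._reads = [r for r in self._reads if id(r) not in drop]
        self._rebuild_index()


def read_from_pysam(aln: pysam.AlignedSegment, sample: str = "") -> Read:
    cigar = tuple(
        (M if op in (7, 8) else op, ln) for op, ln in (aln.cigartuples or ())
    )
    quals = bytes(aln.query_qualities) if aln.query_qualities is not None else b""
    return Read(
        name=aln.query_name or "",
        chrom=aln.reference_name or "",
        pos=aln.reference_start,
        mapq=aln.mapping_quality,
        cigar=cigar,
        seq=aln.query_sequence or "",
        quals=quals,
        is_reverse=aln.is_reverse,
        is_duplicate=aln.is_duplicate,
        is_secondary=aln.is_secondary,
        is_supplementary=aln.is_supplementary,
        sample=sample,
    )


def load_readset(path: str, sample: str = "") -> ReadSet:
    """Read a whole SAM/BAM file into memory as a :class:`ReadSet`."""
    mode = "r" if str(path).endswith(".sam") else "rb"
    reads = []
    with pysam.AlignmentFile(str(path), mode) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            reads.append(read_from_pysam(aln, sample=sample))
    return ReadSet(reads, sample=sample)


def write_alignments(
    reads: Iterable[Read],
    path: str,
    references: Sequence[Tuple[str, int]],
    sample: str,
) -> None:
    """Write reads as coordinate-sorted SAM or indexed BAM (by extension)."""
    path = str(path)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in references],
        "RG": [{"ID": sample, "SM": sample}],
    }
    tid = {name: i for i, (name, _) in enumerate(references)}
    is_sam = path.endswith(".sam")
    with pysam.AlignmentFile(path, "w" if is_sam else "wb", header=header) as out:
        for r in sorted(reads, key=lambda x: (tid[x.chrom], x.pos)):
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.name
            a.reference_id = tid[r.chrom]
            a.reference_start = r.pos
            a.mapping_quality = r.mapq
            a.cigartuples = list(r.cigar)
            a.query_sequence = r.seq
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.quals)
            )
            a.is_reverse = r.is_reverse
            a.is_duplicate = r.is_duplicate
            a.is_secondary = r.is_secondary
            a.is_supplementary = r.is_supplementary
            a.set_tag("RG", sample)
            out.write(a)
    if not is_sam:
        pysam.index(path)
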