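"""Homopolymer and short-tandem-repeat (STR) context of candidate indel sites.

Indel calling is error-prone inside low-complexity sequence: polymerase
slippage during library preparation and ambiguous gap placement during
alignment both concentrate false indel calls in homopolymer runs and short
tandem repeats.  This module detects perfect tandem repeats on the reference
and turns them into two site-level features for the de novo indel filter:

* homopolymer — a run of a single base (unit 1 bp), reported when the tract
  reaches at least 4 copies (= 4 bases);
* STR — a perfect tandem repeat with a primitive unit of 2-6 bp, reported
  when at least 3 complete copies are present.

Only perfect repeats with primitive units are reported: ``AAAA`` is a
homopolymer, never additionally an ``AA`` x 2 STR, and ``ACACAC`` is
``AC`` x 3, never ``ACAC`` x 1.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Mapping, Optional, Set

__all__ = [
    "RepeatInterval",
    "RepeatAnnotation",
    "find_perfect_repeats",
    "annotate_site",
    "HOMOPOLYMER_MIN_COPIES",
    "STR_MIN_COPIES",
    "DEFAULT_FLANK",
]

HOMOPOLYMER_MIN_COPIES = 4
STR_MIN_COPIES = 3
DEFAULT_FLANK = 10

_VALID = frozenset("ACGTN")


@dataclass(frozen=True, order=True)
class RepeatInterval:
    """A maximal perfect tandem repeat on one sequence.

    ``start``/``end`` are 0-based half-open offsets; ``unit_seq`` is the
    primitive repeat unit and ``end - start == unit_size * copy_count``.
    """

    start: int
    unit_size: int
    end: int
    unit_seq: str
    copy_count: int
    chrom: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start != self.unit_size * self.copy_count:
            raise ValueError(
                f"inconsistent repeat interval: [{self.start},{self.end}) "
                f"vs {self.unit_size} x {self.copy_count}"
            )

    @property
    def tract_length(self) -> int:
        """Tract length in bases."""
        return self.end - self.start


@dataclass(frozen=True)
class RepeatAnnotation:
    """Repeat context of a single site, one flag per feature class.

    ``is_homopolymer`` / ``is_str`` record whether a qualifying unit-1 run
    (tract >= 4) or a unit 2-6 repeat (>= 3 copies) overlaps the annotation
    window; the length fields are 0 whenever the corresponding flag is False.
    """

    is_homopolymer: bool
    homopolymer_tract_length: int
    is_str: bool
    str_unit_size: int
    str_copy_count: int

    def __post_init__(self) -> None:
        if self.is_homopolymer and self.homopolymer_tract_length < HOMOPOLYMER_MIN_COPIES:
            raise ValueError("homopolymer tract below minimum of 4")
        if self.is_str and not (2 <= self.str_unit_size <= 6 and self.str_copy_count >= STR_MIN_COPIES):
            raise ValueError("STR annotation violates unit 2-6 / >= 3 copies rule")
        if not self.is_homopolymer and self.homopolymer_tract_length != 0:
            raise ValueError("non-homopolymer site must have zero tract length")
        if not self.is_str and (self.str_unit_size != 0 or self.str_copy_count != 0):
            raise ValueError("non-STR site must have zeroed STR fields")


NO_REPEAT = RepeatAnnotation(False, 0, False, 0, 0)


def _validate_alphabet(sequence: str) -> None:
    for offset, base in enumerate(sequence):
        if base not in _VALID:
            raise ValueError(
                f"invalid nucleotide {base!r} at offset {offset}: "
                "sequence must be over ACGTN"
            )


def _is_primitive(unit: str) -> bool:
    """True when ``unit`` is not a whole-number repetition of a shorter string."""
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def find_perfect_repeats(
    sequence: str,
    unit_min: int = 1,
    unit_max: int = 6,
    min_copies: int = 2,
    chrom: str = "",
    offset: int = 0,
) -> List[RepeatInterval]:
    """Enumerate every maximal perfect tandem repeat in ``sequence``.

    A repeat qualifies when its primitive unit has size in
    ``[unit_min, unit_max]`` and at least ``min_copies`` complete copies are
    present; the reported interval covers complete copies only and cannot be
    extended by one further unit copy on either side within the sequence.
    Tracts containing ``N`` are never reported.  Output is sorted by
    ``(start, unit_size)``.

    ``offset`` shifts reported coordinates (used when scanning a slice of a
    chromosome); ``chrom`` is carried through verbatim.
    """
    sequence = sequence.upper()
    _validate_alphabet(sequence)
    if not (1 <= unit_min <= unit_max <= 6):
        raise ValueError(f"unit sizes must satisfy 1 <= {unit_min} <= {unit_max} <= 6")
    if min_copies < 2:
        raise ValueError(f"min_copies must be >= 2, got {min_copies}")

    n = len(sequence)
    out: Set[RepeatInterval] = set()
    for u in range(unit_min, unit_max + 1):
        # eq[i] marks s[i] == s[i+u]; a maximal True-run [a, b) is a
        # maximal stretch s[a : b+u] periodic with period u.
        i = 0
        limit = n - u
        while i < limit:
            a = i
            while i < limit and sequence[i] == sequence[i + u] and sequence[i] != "N":
                i += 1
            if i == a:
                i += 1
                continue
            b = i  # run is [a, b)
            total = b - a + u  # length of the periodic stretch
            # Each phase k < u yields a distinct maximal complete-copy
            # interval; k beyond total % u cannot reach max copies but may
            # still clear min_copies with one fewer copy — enumerate k < u.
            for k in range(min(u, total - u * min_copies + 1)):
                copies = (total - k) // u
                if copies < min_copies:
                    continue
                unit = sequence[a + k : a + k + u]
                if "N" in unit or not _is_primitive(unit):
                    continue
                out.add(
                    RepeatInterval(
                        start=a + k + offset,
                        unit_size=u,
                        end=a + k + u * copies + offset,
                        unit_seq=unit,
                        copy_count=copies,
                        chrom=chrom,
                    )
                )
    return sorted(out, key=lambda r: (r.start, r.unit_size))


def _best(intervals: Iterable[RepeatInterval]) -> Optional[RepeatInterval]:
    # longest tract, then smaller unit, then leftmost start
    return min(
        intervals,
        key=lambda r: (-r.tract_length, r.unit_size, r.start),
        default=None,
    )


def annotate_site(
    reference: Mapping[str, str],
    chrom: str,
    pos: int,
    flank: int = DEFAULT_FLANK,
    hp_min_copies: int = HOMOPOLYMER_MIN_COPIES,
    str_min_copies: int = STR_MIN_COPIES,
) -> RepeatAnnotation:
    """Annotate the repeat context of a 1-based site on an indexed genome.

    ``reference`` is any chromosome-name-to-sequence mapping (a
    :class:`pyfaidx.Fasta` works).  A feature is flagged when a qualifying
    repeat interval overlaps the closed 1-based window
    ``[pos - flank, pos + flank]``; the homopolymer and STR features are
    annotated independently, each reporting its longest overlapping tract
    (ties: smaller unit size, then leftmost start).
    """
    if flank < 1:
        raise ValueError(f"flank must be >= 1, got {flank}")
    if chrom not in reference:
        raise KeyError(f"unknown chromosome {chrom!r}")
    chrom_seq = reference[chrom]
    chrom_len = len(chrom_seq)
    if not (1 <= pos <= chrom_len):
        raise ValueError(f"position {chrom}:{pos} outside chromosome of length {chrom_len}")

    # 0-based closed annotation window
    w_lo, w_hi = pos - 1 - flank, pos - 1 + flank
    # Scan an extended slice so tracts reaching into the window from outside
    # are seen whole; grow the pad until no reported tract is truncated.
    pad = 200
    while True:
        lo = max(0, w_lo - pad)
        hi = min(chrom_len, w_hi + 1 + pad)
        seq = str(chrom_seq[lo:hi]).upper()
        intervals = [
            r
            for r in find_perfect_repeats(seq, 1, 6, 2, chrom=chrom, offset=lo)
            if r.start <= w_hi and r.end > w_lo
        ]
        truncated = any(
            (r.start == lo and lo > 0) or (r.end == hi and hi < chrom_len)
            for r in intervals
        )
        if not truncated:
            break
        pad *= 2

    hp = _best(r for r in intervals if r.unit_size == 1 and r.copy_count >= hp_min_copies)
    st = _best(r for r in intervals if 2 <= r.unit_size <= 6 and r.copy_count >= str_min_copies)
    return RepeatAnnotation(
        is_homopolymer=hp is not None,
        homopolymer_tract_length=hp.tract_length if hp else 0,
        is_str=st is not None,
        str_unit_size=st.unit_size if st else 0,
        str_copy_count=st.copy_count if st else 0,
    )
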