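"""Fully synthetic, ground-truthed trio sequencing data.

The simulator produces everything the filter pipeline consumes — a
reference with planted homopolymer/STR tracts, Mendelian trio genotypes
with planted de novo indels, and pre-aligned reads with substitution errors
and repeat-slippage indel artifacts — together with a complete truth table,
so that every module is testable without external data.

Reads are emitted pre-aligned: alignment coordinates and CIGARs are derived
from the known haplotype-to-reference mapping rather than from a real
aligner, which keeps the data hermetic and the truth exact.  Planted de novo
and inherited indel sites are placed in non-repetitive background sequence,
well separated from one another; artifact sites sit inside planted repeat
tracts and carry no true variant in any member — a configurable fraction of
one member's reads instead acquires a 1-2 bp slippage indel there, mimicking
the repeat-region errors that dominate false de novo indel calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from .reads import D, I, M, S, Read, ReadSet, write_alignments
from .repeats import RepeatInterval
from .variants import ROLES, CandidateIndel, Pedigree, normalize_indel

__all__ = ["SimConfig", "TrioTruth", "TrioSimulation", "simulate_reference",
           "simulate_trio", "simulate_reads", "run_simulation"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
DEFAULT_QUAL = 35
DEFAULT_MAPQ = 60


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated trio."""

    ref_length: int = 200_000
    n_homopolymers: int = 40
    n_strs: int = 40
    n_inherited_indels: int = 60
    n_denovo_indels: int = 10
    n_artifact_sites: int = 30
    coverage: float = 30.0
    read_length: int = 100
    base_error_rate: float = 0.002
    seed: int = 0
    chrom: str = "chr1"

    def __post_init__(self):
        if min(self.n_homopolymers, self.n_strs, self.n_inherited_indels,
               self.n_denovo_indels, self.n_artifact_sites) < 0:
            raise ValueError("all site counts must be >= 0")
        if not (0 <= self.base_error_rate < 0.5):
            raise ValueError("base_error_rate must be in [0, 0.5)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


@dataclass
class TrioTruth:
    """Ground truth: per-site trio genotypes, de novo and artifact flags,
    and the planted repeat intervals."""

    sites: pd.DataFrame  # chrom pos ref alt father_gt mother_gt offspring_gt is_denovo is_artifact artifact_member
    repeats: List[RepeatInterval]

    def denovo_sites(self) -> List[CandidateIndel]:
        return self._to_sites(self.sites[self.sites.is_denovo])

    def artifact_sites(self) -> List[CandidateIndel]:
        return self._to_sites(self.sites[self.sites.is_artifact])

    def inherited_sites(self) -> List[CandidateIndel]:
        mask = (~self.sites.is_denovo) & (~self.sites.is_artifact) & (self.sites.offspring_gt == "0/1")
        return self._to_sites(self.sites[mask])

    @staticmethod
    def _to_sites(df: pd.DataFrame) -> List[CandidateIndel]:
        return [CandidateIndel(r.chrom, int(r.pos), r.ref, r.alt) for r in df.itertuples()]

    def genotype_records(self) -> List[dict]:
        """Truth genotypes of the non-artifact sites in the record format
        used for swap-site discovery (same layout as
        :func:`dnmindel.variants.read_trio_genotypes`)."""
        out = []
        for r in self.sites[~self.sites.is_artifact].itertuples():
            out.append(
                {
                    "site": CandidateIndel(r.chrom, int(r.pos), r.ref, r.alt),
                    "father": tuple(int(a) for a in r.father_gt.split("/")),
                    "mother": tuple(int(a) for a in r.mother_gt.split("/")),
                    "offspring": tuple(int(a) for a in r.offspring_gt.split("/")),
                }
            )
        return out


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _primitive_unit(rng: np.random.Generator, size: int) -> str:
    while True:
        u = _random_seq(rng, size)
        if size == 1:
            return u
        if all(not (size % d == 0 and u == u[:d] * (size // d)) for d in range(1, size)):
            return u


def simulate_reference(config: SimConfig) -> Tuple[str, List[RepeatInterval]]:
    """Random background with non-overlapping planted repeat tracts.

    Homopolymers get tracts of 4-15 bases, STRs primitive units of 2-6 bp
    with 3-10 copies.  The bases immediately flanking each plant are forced
    to break the repeat so the planted tract lengths are exact.
    """
    rng = np.random.default_rng(config.seed)
    seq = list(_random_seq(rng, config.ref_length))
    n_plants = config.n_homopolymers + config.n_strs
    max_len = 6 * 10 + 2
    if n_plants * (max_len + 20) > config.ref_length * 0.8:
        raise ValueError(
            f"cannot place {n_plants} repeats in a {config.ref_length} bp reference"
        )

    planted: List[RepeatInterval] = []
    occupied: List[Tuple[int, int]] = []

    def place(length: int) -> Optional[int]:
        for _ in range(200):
            start = int(rng.integers(1, config.ref_length - length - 1))
            if all(start + length + 2 <= s or start >= e + 2 for s, e in occupied):
                return start
        return None

    kinds = ["hp"] * config.n_homopolymers + ["str"] * config.n_strs
    for kind in kinds:
        if kind == "hp":
            unit = _primitive_unit(rng, 1)
            copies = int(rng.integers(4, 16))
        else:
            unit = _primitive_unit(rng, int(rng.integers(2, 7)))
            copies = int(rng.integers(3, 11))
        tract = unit * copies
        start = place(len(tract))
        if start is None:
            raise ValueError(
                f"could not place repeat of {len(tract)} bp after planting "
                f"{len(planted)} of {n_plants}"
            )
        seq[start : start + len(tract)] = tract
        # flanking guards: first mismatching base kills any extension
        others_l = [b for b in "ACGT" if b != unit[-1]]
        others_r = [b for b in "ACGT" if b != unit[0]]
        seq[start - 1] = others_l[int(rng.integers(len(others_l)))]
        seq[start + len(tract)] = others_r[int(rng.integers(len(others_r)))]
        occupied.append((start, start + len(tract)))
        planted.append(
            RepeatInterval(
                start=start,
                unit_size=len(unit),
                end=start + len(tract),
                unit_seq=unit,
                copy_count=copies,
                chrom=config.chrom,
            )
        )
    planted.sort(key=lambda r: r.start)
    return "".join(seq), planted


# ---------------------------------------------------------------------------
# genotypes / haplotypes


@dataclass
class _Variant:
    site: CandidateIndel  # normalized

    @property
    def anchor0(self) -> int:
        return self.site.pos - 1


def _draw_indel(rng: np.random.Generator, reference: str, chrom: str, pos1: int) -> CandidateIndel:
    """Random 1-6 bp insertion or deletion anchored at 1-based ``pos1``."""
    length = int(rng.integers(1, 7))
    anchor = reference[pos1 - 1]
    if rng.random() < 0.5 and pos1 + length <= len(reference):
        ref, alt = reference[pos1 - 1 : pos1 + length], anchor  # deletion
    else:
        ref, alt = anchor, anchor + _random_seq(rng, length)  # insertion
    return normalize_indel(chrom, pos1, ref, alt, {chrom: reference})


def simulate_trio(
    reference: str, config: SimConfig, repeats: Optional[List[RepeatInterval]] = None
) -> Tuple[Dict[str, Tuple[List[_Variant], List[_Variant]]], TrioTruth]:
    """Plant inherited, de novo and artifact sites and draw trio genotypes.

    Returns per-member haplotype variant lists (two haplotypes per member;
    offspring haplotype 0 is paternal, 1 maternal) and the truth table.
    Inherited indels are heterozygous in one random parent and transmitted
    by a fair coin; de novo indels are heterozygous in the offspring only;
    artifact sites carry no variant and sit inside planted repeats.
    """
    rng = np.random.default_rng(config.seed + 1)
    repeats = repeats or []
    spacing = config.read_length + 24
    min_pos = config.read_length + 10
    max_pos = len(reference) - config.read_length - 10
    if max_pos <= min_pos:
        raise ValueError("reference too short for the configured read length")

    blocked = [(r.start - spacing, r.end + spacing) for r in repeats]

    def in_blocked(p0: int) -> bool:
        return any(s <= p0 < e for s, e in blocked)

    n_var = config.n_inherited_indels + config.n_denovo_indels
    positions: List[int] = []
    taken: List[int] = []
    attempts = 0
    while len(positions) < n_var:
        attempts += 1
        if attempts > 200 * max(n_var, 1):
            raise ValueError(
                f"could not place {n_var} variant sites with {spacing} bp spacing"
            )
        p = int(rng.integers(min_pos, max_pos))
        if in_blocked(p):
            continue
        if all(abs(p - q) >= spacing for q in taken):
            positions.append(p)
            taken.append(p)
    positions.sort()
    flags = ["inh"] * config.n_inherited_indels + ["dnm"] * config.n_denovo_indels
    rng.shuffle(flags)  # type: ignore[arg-type]

    haplotypes: Dict[str, Tuple[List[_Variant], List[_Variant]]] = {
        role: ([], []) for role in ROLES
    }
    rows = []
    for p0, flag in zip(positions, flags):
        site = _draw_indel(rng, reference, config.chrom, p0 + 1)
        gts = {"father": "0/0", "mother": "0/0", "offspring": "0/0"}
        if flag == "dnm":
            gts["offspring"] = "0/1"
            hap = int(rng.integers(2))
            haplotypes["offspring"][hap].append(_Variant(site))
        else:
            parent = "father" if rng.random() < 0.5 else "mother"
            gts[parent] = "0/1"
            carrier_hap = int(rng.integers(2))
            haplotypes[parent][carrier_hap].append(_Variant(site))
            if rng.random() < 0.5:  # fair transmission
                gts["offspring"] = "0/1"
                child_hap = 0 if parent == "father" else 1
                haplotypes["offspring"][child_hap].append(_Variant(site))
        rows.append(
            dict(
                chrom=site.chrom, pos=site.pos, ref=site.ref_allele, alt=site.alt_allele,
                father_gt=gts["father"], mother_gt=gts["mother"],
                offspring_gt=gts["offspring"],
                is_denovo=flag == "dnm", is_artifact=False, artifact_member="",
            )
        )

    # artifact sites: inside planted repeats, no true variant anywhere
    eligible = [r for r in repeats if min_pos < r.start and r.end < max_pos]
    if config.n_artifact_sites > len(eligible):
        raise ValueError(
            f"requested {config.n_artifact_sites} artifact sites but only "
            f"{len(eligible)} planted repeats are available"
        )
    chosen = rng.choice(len(eligible), size=config.n_artifact_sites, replace=False)
    for idx in sorted(int(i) for i in chosen):
        rep = eligible[idx]
        alen = 1 if rep.unit_size == 1 else min(rep.unit_size, 2)
        apos0 = rep.start  # slippage at the tract start
        anchor = reference[apos0 - 1]
        if rng.random() < 0.5 and rep.tract_length >= alen:
            ref_a, alt_a = reference[apos0 - 1 : apos0 + alen], anchor  # deletion
            etype = "D"
        else:
            ref_a, alt_a = anchor, anchor + reference[apos0 : apos0 + alen]  # duplication
            etype = "I"
        site = normalize_indel(config.chrom, apos0, ref_a, alt_a, {config.chrom: reference})
        member = ROLES[int(rng.integers(3))]
        rows.append(
            dict(
                chrom=site.chrom, pos=site.pos, ref=site.ref_allele, alt=site.alt_allele,
                father_gt="0/0", mother_gt="0/0", offspring_gt="0/0",
                is_denovo=False, is_artifact=True, artifact_member=member,
            )
        )

    truth = pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    if truth.duplicated(["chrom", "pos", "ref", "alt"]).any():
        truth = truth.drop_duplicates(["chrom", "pos", "ref", "alt"]).reset_index(drop=True)
    return haplotypes, TrioTruth(sites=truth, repeats=list(repeats))


# ---------------------------------------------------------------------------
# reads


def _build_haplotype(reference: str, variants: List[_Variant]):
    """Haplotype sequence plus contiguous alignment blocks.

    Returns (hapseq, blocks) where blocks is a list of
    (hap_start, hap_end, ref_start) for maximal stretches that map
    contiguously to the reference; insertion bases map to ref_start = -1.
    """
    variants = sorted(variants, key=lambda v: v.site.pos)
    pieces: List[str] = []
    blocks: List[Tuple[int, int, int]] = []
    ref_cur = 0
    hap_cur = 0

    def emit(seq_piece: str, ref_start: int):
        nonlocal hap_cur
        if seq_piece:
            blocks.append((hap_cur, hap_cur + len(seq_piece), ref_start))
            pieces.append(seq_piece)
            hap_cur += len(seq_piece)

    for v in variants:
        s = v.site
        a0 = s.pos - 1  # anchor, 0-based
        emit(reference[ref_cur : a0 + 1], ref_cur)  # up to and including anchor
        ref_cur = a0 + 1
        if s.indel_type == "deletion":
            ref_cur += s.indel_length  # skip deleted bases
        else:
            emit(s.alt_allele[1:], -1)  # inserted bases
    emit(reference[ref_cur:], ref_cur)
    return "".join(pieces), blocks


def _cigar_for(blocks, bi: int, s: int, length: int):
    """Alignment (ref_pos, cigar) for a haplotype interval [s, s+length)
    starting inside block ``bi``."""
    ops: List[Tuple[int, int]] = []
    ref_pos = None
    remaining = length
    pos = s
    i = bi
    while remaining > 0 and i < len(blocks):
        b_start, b_end, r_start = blocks[i]
        take = min(remaining, b_end - pos)
        if r_start < 0:
            op = (I, take)
        else:
            op = (M, take)
            if ref_pos is None:
                ref_pos = r_start + (pos - b_start)
        if ops and ops[-1][0] == op[0]:
            ops[-1] = (op[0], ops[-1][1] + op[1])
        else:
            ops.append(op)
        # deletion gap between this block and the next contiguous one
        remaining -= take
        pos += take
        if pos == b_end and remaining > 0 and i + 1 < len(blocks):
            nb_start, nb_end, nr_start = blocks[i + 1]
            if r_start >= 0 and nr_start >= 0:
                gap = nr_start - (r_start + (b_end - b_start))
                if gap > 0:
                    ops.append((D, gap))
            i += 1
            pos = nb_start
        elif pos == b_end:
            i += 1
            pos = blocks[i][0] if i < len(blocks) else pos
    if ref_pos is None:  # read entirely inside an insertion (should not happen)
        raise ValueError("read maps to no reference base")
    # leading insertions cannot be placed; convert to soft clips
    if ops and ops[0][0] == I:
        ops[0] = (S, ops[0][1])
    if ops and ops[-1][0] == I:
        ops[-1] = (S, ops[-1][1])
    # trailing deletion makes no sense
    if ops and ops[-1][0] == D:
        ops.pop()
    return ref_pos, tuple(ops)


def simulate_reads(
    haplotypes: Mapping[str, Tuple[List[_Variant], List[_Variant]]],
    reference: str,
    config: SimConfig,
    truth: Optional[TrioTruth] = None,
) -> Dict[str, ReadSet]:
    """Draw reads uniformly along each haplotype at half the target coverage
    per haplotype, add substitution errors, and inject slippage indels into
    the designated member's reads at each artifact site."""
    if config.read_length > len(reference):
        raise ValueError("read_length exceeds reference length")
    rng = np.random.default_rng(config.seed + 2)
    L = config.read_length
    shared_quals = bytes([DEFAULT_QUAL]) * L
    readsets: Dict[str, ReadSet] = {}

    for role in ROLES:
        member_reads: List[Read] = []
        for h in (0, 1):
            hapseq, blocks = _build_haplotype(reference, haplotypes[role][h])
            hap_len = len(hapseq)
            n_reads = int(round(config.coverage / 2 * hap_len / L))
            starts = np.sort(rng.integers(0, hap_len - L + 1, size=n_reads))
            block_starts = np.array([b[0] for b in blocks])
            block_idx = np.searchsorted(block_starts, starts, side="right") - 1
            reverse = rng.random(n_reads) < 0.5
            # substitution errors, globally drawn
            n_err = rng.binomial(n_reads * L, config.base_error_rate)
            err_reads = rng.integers(0, n_reads, size=n_err)
            err_offs = rng.integers(0, L, size=n_err)
            err_map: Dict[int, List[int]] = {}
            for ri, off in zip(err_reads, err_offs):
                err_map.setdefault(int(ri), []).append(int(off))

            for i in range(n_reads):
                s = int(starts[i])
                bi = int(block_idx[i])
                b_start, b_end, r_start = blocks[bi]
                seq = hapseq[s : s + L]
                if s + L <= b_end and r_start >= 0:
                    pos, cigar = r_start + (s - b_start), ((M, L),)
                else:
                    pos, cigar = _cigar_for(blocks, bi, s, L)
                if i in err_map:
                    sl = list(seq)
                    for off in err_map[i]:
                        cur = sl[off]
                        sl[off] = "ACGT"[(("ACGT".index(cur) if cur in "ACGT" else 0) + int(rng.integers(1, 4))) % 4]
                    seq = "".join(sl)
                member_reads.append(
                    Read(
                        name=f"{role}.{h}.{i}",
                        chrom=config.chrom,
                        pos=pos,
                        mapq=DEFAULT_MAPQ,
                        cigar=cigar,
                        seq=seq,
                        quals=shared_quals if len(seq) == L else bytes([DEFAULT_QUAL]) * len(seq),
                        is_reverse=bool(reverse[i]),
                        sample=role,
                    )
                )
        readsets[role] = ReadSet(member_reads, sample=role)

    if truth is not None:
        _inject_artifacts(readsets, reference, truth, rng)
    return readsets


def _inject_artifacts(
    readsets: Dict[str, ReadSet],
    reference: str,
    truth: TrioTruth,
    rng: np.random.Generator,
) -> None:
    """Give 10-30% of one member's reads a slippage indel at each artifact
    site (cigar/sequence surgery on reads with a pure-match alignment)."""
    art = truth.sites[truth.sites.is_artifact]
    for row in art.itertuples():
        member = row.artifact_member
        site = CandidateIndel(row.chrom, int(row.pos), row.ref, row.alt)
        is_del = site.indel_type == "deletion"
        d = site.indel_length
        apos0 = site.pos  # first deleted base / insertion point (0-based)
        frac = rng.uniform(0.1, 0.3)
        for read in readsets[member].fetch(site.chrom, apos0 - 2, apos0 + d + 2):
            if rng.random() >= frac:
                continue
            if read.cigar != ((M, len(read.seq)),):
                continue
            q = apos0 - read.pos
            if is_del:
                if q < 2 or q + d > len(read.seq) - 2:
                    continue
                read.seq = read.seq[:q] + read.seq[q + d :]
                read.cigar = ((M, q), (D, d), (M, len(read.seq) - q))
                read.quals = read.quals[: len(read.seq)]
            else:
                if q < 2 or q > len(read.seq) - d - 2:
                    continue
                ins = site.alt_allele[1:]  # left-aligned inserted bases
                read.seq = (read.seq[:q] + ins + read.seq[q:])[: len(read.seq)]
                read.cigar = ((M, q), (I, d), (M, len(read.seq) - q - d))
    for rs in readsets.values():
        rs._rebuild_index()


# ---------------------------------------------------------------------------
# bundle + writers


DEFAULT_PEDIGREE = Pedigree(father="FATHER", mother="MOTHER", offspring="CHILD")


@dataclass
class TrioSimulation:
    """One simulated trio: reference, truth and per-member reads."""

    config: SimConfig
    reference: str
    truth: TrioTruth
    reads: Dict[str, ReadSet]
    pedigree: Pedigree = field(default_factory=lambda: DEFAULT_PEDIGREE)

    @property
    def reference_map(self) -> Dict[str, str]:
        return {self.config.chrom: self.reference}

    def write_all(self, outdir: str, alignment_format: str = "bam") -> Dict[str, str]:
        """Write FASTA (+index), per-member alignments, truth/candidate
        VCFs, truth TSV and PED into ``outdir``; returns the path map."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        chrom, n = self.config.chrom, len(self.reference)
        paths: Dict[str, str] = {}

        fasta = out / "reference.fa"
        with open(fasta, "w") as fh:
            fh.write(f">{chrom}\n")
            for i in range(0, n, 60):
                fh.write(self.reference[i : i + 60] + "\n")
        pysam.faidx(str(fasta))
        paths["reference"] = str(fasta)

        ext = "sam" if alignment_format == "sam" else "bam"
        for role in ROLES:
            p = out / f"{getattr(self.pedigree, role)}.{ext}"
            write_alignments(self.reads[role], str(p), [(chrom, n)], getattr(self.pedigree, role))
            paths[role] = str(p)

        ped = out / "trio.ped"
        ped.write_text(
            f"{self.pedigree.family}\t{self.pedigree.father}\t0\t0\t1\t1\n"
            f"{self.pedigree.family}\t{self.pedigree.mother}\t0\t0\t2\t1\n"
            f"{self.pedigree.family}\t{self.pedigree.offspring}\t{self.pedigree.father}\t{self.pedigree.mother}\t1\t2\n"
        )
        paths["pedigree"] = str(ped)

        paths["genotypes"] = str(out / "trio_genotypes.vcf")
        self._write_vcf(paths["genotypes"], self.truth.sites[~self.truth.sites.is_artifact])
        paths["candidates"] = str(out / "putative_denovo.vcf")
        cand = self.truth.sites[self.truth.sites.is_denovo | self.truth.sites.is_artifact]
        self._write_vcf(paths["candidates"], cand, genotypes=False)

        tsv = out / "truth_sites.tsv"
        self.truth.sites.to_csv(tsv, sep="\t", index=False)
        paths["truth"] = str(tsv)
        return paths

    def _write_vcf(self, path: str, sites: pd.DataFrame, genotypes: bool = True) -> None:
        header = pysam.VariantHeader()
        header.add_line(f"##contig=<ID={self.config.chrom},length={len(self.reference)}>")
        header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        names = [getattr(self.pedigree, role) for role in ROLES] if genotypes else []
        for name in names:
            header.add_sample(name)
        with pysam.VariantFile(path, "w", header=header) as vcf:
            for row in sites.itertuples():
                rec = vcf.new_record(
                    contig=row.chrom, start=int(row.pos) - 1,
                    alleles=(row.ref, row.alt),
                )
                if genotypes:
                    for role, name in zip(ROLES, names):
                        gt = getattr(row, f"{role}_gt")
                        rec.samples[name]["GT"] = tuple(int(a) for a in gt.split("/"))
                        rec.samples[name].phased = False
                vcf.write(rec)


def run_simulation(config: SimConfig) -> TrioSimulation:
    """Simulate one complete trio under ``config``."""
    reference, repeats = simulate_reference(config)
    haplotypes, truth = simulate_trio(reference, config, repeats)
    reads = simulate_reads(haplotypes, reference, config, truth)
    return TrioSimulation(config=config, reference=reference, truth=truth, reads=reads)
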