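"""Pileup metrics and trio feature-vector extraction on hand-built pileups."""

import pytest

from dnmindel.features import (
    EMPTY_PILEUP_METRICS,
    FEATURE_NAMES,
    METRIC_NAMES,
    compute_sample_metrics,
    count_allele_support,
    extract_trio_features,
    left_align_event,
    schema_fingerprint,
)
from dnmindel.reads import D, I, M, Read, ReadSet, S
from dnmindel.variants import CandidateIndel

# 60 bp reference; the main candidate deletes "AG" at 1-based anchor 20
# (already left-aligned; positions chosen outside any repeat)
#      0         1         2         3         4         5
#      0123456789012345678901234567890123456789012345678901234567890
REF = "GGCTATCGAGCTTGACGTTCAGTCGGACTGTGCATTAACCGGTTGACATGCCTGCATGAC"
REFMAP = {"chr1": REF}

DEL2 = CandidateIndel("chr1", 20, REF[19:22], REF[19])  # deletes AG at 0-based 20..21


def mk_read(pos, cigar, name="r", mapq=60, reverse=False, seq=None, quals=None, **flags):
    length = sum(ln for op, ln in cigar if op in (M, I, S))
    ref_consumed = sum(ln for op, ln in cigar if op in (M, D))
    if seq is None:
        # sequence consistent with the reference and the CIGAR
        parts, rp, = [], pos
        for op, ln in cigar:
            if op == M:
                parts.append(REF[rp : rp + ln])
                rp += ln
            elif op == D:
                rp += ln
            else:
                parts.append("A" * ln)
        seq = "".join(parts)
    return Read(
        name=name, chrom="chr1", pos=pos, mapq=mapq, cigar=tuple(cigar),
        seq=seq, quals=quals or bytes([30]) * len(seq), is_reverse=reverse, **flags,
    )


def alt_read(name, pos=5, reverse=False, mapq=60, **kw):
    # deletion of AG at 0-based 20..21
    return mk_read(pos, [(M, 20 - pos), (D, 2), (M, 20)], name=name,
                   reverse=reverse, mapq=mapq, **kw)


def ref_read(name, pos=5, reverse=False, mapq=60, **kw):
    return mk_read(pos, [(M, 40)], name=name, reverse=reverse, mapq=mapq, **kw)


class TestAlleleSupport:
    def test_counts_matching_deletion_reads(self):
        reads = [ref_read(f"r{i}") for i in range(5)] + [alt_read(f"a{i}") for i in range(5)]
        assert count_allele_support(reads, DEL2, REF) == (10, 5)

    def test_empty_pileup(self):
        assert count_allele_support([], DEL2, REF) == (0, 0)

    def test_left_alignment_reconciles_shifted_events(self):
        # delete one A of the AA run at 0-based 36..37: a read carrying the
        # deletion at 37 describes the same allele and must count as support
        site = CandidateIndel("chr1", 36, REF[35:37], REF[35])  # TA>T, leftmost form
        shifted = mk_read(10, [(M, 27), (D, 1), (M, 13)], name="s")  # deletion at 37
        assert count_allele_support([shifted], site, REF) == (1, 1)

    def test_near_miss_indels_do_not_count_as_alt(self):
        wrong_len = mk_read(5, [(M, 15), (D, 3), (M, 20)], name="w")
        depth, alt = count_allele_support([alt_read("a"), wrong_len], DEL2, REF)
        assert (depth, alt) == (2, 1)

    def test_filters_low_mapq_and_flagged_reads(self):
        reads = [
            ref_read("ok"),
            ref_read("lowq", mapq=5),
            ref_read("dup", is_duplicate=True),
            ref_read("sec", is_secondary=True),
            ref_read("sup", is_supplementary=True),
        ]
        assert count_allele_support(reads, DEL2, REF, min_mapq=20) == (1, 0)

    def test_wrong_chromosome_rejected(self):
        bad = Read("x", "chr2", 5, 60, ((M, 40),), "A" * 40, bytes([30]) * 40)
        with pytest.raises(ValueError, match="chr2"):
            count_allele_support([bad], DEL2, REF)


class TestSampleMetrics:
    def test_hand_built_mixed_pileup(self):
        reads = [ref_read(f"r{i}", reverse=False) for i in range(4)] + [
            alt_read("a0", reverse=True, mapq=20),
            alt_read("a1", reverse=True, mapq=20),
        ]
        m = compute_sample_metrics(reads, DEL2, REF, min_mapq=20)
        assert (m.depth, m.alt_count) == (6, 2)
        assert m.alt_fraction == pytest.approx(1 / 3)
        assert m.mean_mapq_all == pytest.approx((4 * 60 + 2 * 20) / 6)
        assert m.mean_mapq_alt == pytest.approx(20)
        assert m.fwd_alt_fraction == 0.0
        assert m.mean_baseq_flank == pytest.approx(30)
        assert m.softclip_fraction == 0.0
        assert m.other_indel_count == 0

    def test_empty_pileup_defaults(self):
        assert compute_sample_metrics([], DEL2, REF) == EMPTY_PILEUP_METRICS
        assert EMPTY_PILEUP_METRICS.fwd_alt_fraction == 0.5

    def test_all_ref_pileup_defaults(self):
        m = compute_sample_metrics([ref_read(f"r{i}") for i in range(3)], DEL2, REF)
        assert (m.alt_fraction, m.fwd_alt_fraction, m.mean_mapq_alt) == (0.0, 0.5, 0.0)

    def test_softclip_and_mismatch_fractions(self):
        clipped = mk_read(10, [(S, 5), (M, 30)], name="c")
        noisy = mk_read(5, [(M, 40)], name="n", seq="T" * 40)  # many mismatches
        m = compute_sample_metrics([clipped, noisy, ref_read("r")], DEL2, REF)
        assert m.softclip_fraction == pytest.approx(1 / 3)
        assert m.mismatch_fraction == pytest.approx(1 / 3)

    def test_other_indel_alleles_counted_distinctly(self):
        others = [
            mk_read(5, [(M, 15), (D, 3), (M, 20)], name="w1"),
            mk_read(6, [(M, 14), (D, 3), (M, 20)], name="w2"),  # same allele
            mk_read(5, [(M, 17), (I, 2), (M, 20)], name="w3"),  # different allele
        ]
        m = compute_sample_metrics(others + [alt_read("a")], DEL2, REF)
        assert m.other_indel_count == 2

    def test_input_order_invariance(self):
        reads = [ref_read(f"r{i}") for i in range(4)] + [alt_read("a", reverse=True)]
        assert compute_sample_metrics(reads, DEL2, REF) == compute_sample_metrics(
            list(reversed(reads)), DEL2, REF
        )


class TestTrioExtraction:
    def trio(self):
        return {
            "father": ReadSet([ref_read(f"f{i}") for i in range(4)], sample="F"),
            "mother": ReadSet([ref_read(f"m{i}") for i in range(4)], sample="M"),
            "offspring": ReadSet(
                [ref_read(f"o{i}") for i in range(2)] + [alt_read(f"oa{i}") for i in range(2)],
                sample="O",
            ),
        }

    def test_schema_contract_37_named_values(self):
        fv = extract_trio_features(self.trio(), DEL2, REFMAP)
        assert len(fv.values) == 37
        assert tuple(fv.values) == FEATURE_NAMES
        assert len(FEATURE_NAMES) == 3 * len(METRIC_NAMES) + 7

    def test_denovo_signature_and_site_features(self):
        fv = extract_trio_features(self.trio(), DEL2, REFMAP)
        assert fv.values["offspring_alt_fraction"] == pytest.approx(0.5)
        assert fv.values["father_alt_fraction"] == 0.0
        assert fv.values["mother_alt_fraction"] == 0.0
        assert fv.values["indel_length"] == 2.0
        assert fv.values["indel_type_code"] == 0.0  # deletion

    def test_extraction_deterministic(self):
        a = extract_trio_features(self.trio(), DEL2, REFMAP)
        b = extract_trio_features(self.trio(), DEL2, REFMAP)
        assert a.values == b.values

    def test_removing_alt_reads_zeroes_alt_fraction(self):
        trio = self.trio()
        trio["offspring"] = ReadSet([ref_read(f"o{i}") for i in range(4)], sample="O")
        fv = extract_trio_features(trio, DEL2, REFMAP)
        assert fv.values["offspring_alt_fraction"] == 0.0

    def test_missing_role_rejected(self):
        trio = self.trio()
        del trio["mother"]
        with pytest.raises(ValueError, match="mother"):
            extract_trio_features(trio, DEL2, REFMAP)

    def test_fingerprint_stable(self):
        assert schema_fingerprint() == schema_fingerprint(FEATURE_NAMES)
        assert schema_fingerprint(("a", "b")) != schema_fingerprint(("b", "a"))


class TestLeftAlignEvent:
    def test_deletion_shifts_through_repeat(self):
        #            0123456789
        chrom_seq = "GGAAAATTGC"
        assert left_align_event("D", 5, 1, "", chrom_seq) == 2
        assert left_align_event("D", 2, 2, "", chrom_seq) == 2

    def test_insertion_rotates_to_leftmost_point(self):
        chrom_seq = "GGAAAATTGC"
        assert left_align_event("I", 6, 1, "A", chrom_seq) == 2
        assert left_align_event("I", 2, 2, "AG", chrom_seq) == 1
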