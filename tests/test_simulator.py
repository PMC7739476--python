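"""Simulator truth: planted repeats, Mendelian genotypes, read fidelity."""

import numpy as np
import pytest

from dnmindel.features import _mismatches, compute_sample_metrics
from dnmindel.repeats import find_perfect_repeats
from dnmindel.simulate import (
    SimConfig,
    run_simulation,
    simulate_reads,
    simulate_reference,
    simulate_trio,
)
from dnmindel.variants import CandidateIndel

SMALL = SimConfig(
    ref_length=60_000, n_homopolymers=15, n_strs=15, n_inherited_indels=30,
    n_denovo_indels=8, n_artifact_sites=10, coverage=25, seed=123,
)


@pytest.fixture(scope="module")
def sim():
    return run_simulation(SMALL)


class TestReference:
    def test_planted_repeats_recovered_by_detector(self, sim):
        found = {
            (r.start, r.end, r.unit_seq)
            for r in find_perfect_repeats(sim.reference, 1, 6, 3)
        }
        planted = {
            (r.start, r.end, r.unit_seq)
            for r in sim.truth.repeats
            if r.copy_count >= (4 if r.unit_size == 1 else 3)
        }
        assert planted <= found

    def test_seeded_reproducibility(self):
        cfg = SimConfig(ref_length=5_000, n_homopolymers=0, n_strs=0, seed=9)
        assert simulate_reference(cfg)[0] == simulate_reference(cfg)[0]

    def test_infeasible_placement_rejected(self):
        cfg = SimConfig(ref_length=200, n_homopolymers=50, n_strs=50)
        with pytest.raises(ValueError, match="place"):
            simulate_reference(cfg)


def alleles_of(gt):
    return [int(a) for a in gt.split("/")]


class TestTrioGenotypes:
    def test_mendelian_consistency_except_flagged_denovo(self, sim):
        for row in sim.truth.sites.itertuples():
            if row.is_denovo or row.is_artifact:
                continue
            kid = sorted(alleles_of(row.offspring_gt))
            dad = alleles_of(row.father_gt)
            mum = alleles_of(row.mother_gt)
            assert any(
                sorted([a, b]) == kid for a in dad for b in mum
            ), f"non-Mendelian at {row.pos}"

    def test_denovo_sites_parents_ref_offspring_het(self, sim):
        dn = sim.truth.sites[sim.truth.sites.is_denovo]
        assert len(dn) == SMALL.n_denovo_indels
        assert (dn.father_gt == "0/0").all()
        assert (dn.mother_gt == "0/0").all()
        assert (dn.offspring_gt == "0/1").all()

    def test_artifact_sites_overlap_repeats_and_carry_no_variant(self, sim):
        art = sim.truth.sites[sim.truth.sites.is_artifact]
        assert len(art) == SMALL.n_artifact_sites
        for row in art.itertuples():
            assert row.father_gt == row.mother_gt == row.offspring_gt == "0/0"
            assert any(
                r.start - 10 <= row.pos - 1 <= r.end + 10 for r in sim.truth.repeats
            )
            assert row.artifact_member in ("father", "mother", "offspring")

    def test_transmission_frequency_fair_over_many_sites(self):
        cfg = SimConfig(
            ref_length=400_000, n_homopolymers=0, n_strs=0,
            n_inherited_indels=2000, n_denovo_indels=0, n_artifact_sites=0, seed=77,
        )
        ref, reps = simulate_reference(cfg)
        _, truth = simulate_trio(ref, cfg, reps)
        inherited = truth.sites[~truth.sites.is_denovo]
        rate = (inherited.offspring_gt == "0/1").mean()
        # binomial(2000, 0.5): 4 sigma ~ 0.045
        assert abs(rate - 0.5) < 0.045


class TestReads:
    def test_zero_error_reads_match_reference_outside_indels(self):
        cfg = SimConfig(
            ref_length=30_000, n_homopolymers=5, n_strs=5, n_inherited_indels=10,
            n_denovo_indels=3, n_artifact_sites=0, coverage=10,
            base_error_rate=0.0, seed=5,
        )
        ref, reps = simulate_reference(cfg)
        haps, truth = simulate_trio(ref, cfg, reps)
        reads = simulate_reads(haps, ref, cfg, truth)
        for role, rs in reads.items():
            for r in rs:
                assert _mismatches(r, ref) == 0, (role, r.name)

    def test_mean_depth_near_target_coverage(self, sim):
        rng = np.random.default_rng(0)
        depths = []
        for pos in rng.integers(5_000, 55_000, size=60):
            pile = sim.reads["father"].fetch("chr1", int(pos), int(pos) + 1)
            depths.append(len(pile))
        assert abs(np.mean(depths) - SMALL.coverage) < 3

    def test_artifact_site_shows_spurious_indel_reads(self, sim):
        art = sim.truth.sites[sim.truth.sites.is_artifact]
        n_with_alt = 0
        for row in art.itertuples():
            site = CandidateIndel(row.chrom, int(row.pos), row.ref, row.alt)
            pile = sim.reads[row.artifact_member].fetch(row.chrom, site.pos - 1, site.pos + 2)
            m = compute_sample_metrics(pile, site, sim.reference)
            if m.alt_count >= 1:
                n_with_alt += 1
        # injection fractions of 0.1-0.3 leave a small per-site chance of an
        # empty alt pileup at this depth; require a clear majority
        assert n_with_alt >= 0.7 * len(art)

    def test_read_length_exceeding_reference_rejected(self):
        cfg = SimConfig(ref_length=2_000, n_homopolymers=0, n_strs=0, read_length=5_000)
        with pytest.raises(ValueError, match="read_length|reference"):
            ref, reps = simulate_reference(cfg)
            haps, truth = simulate_trio(ref, cfg, reps)

    def test_byte_reproducible_per_seed(self):
        cfg = SimConfig(
            ref_length=15_000, n_homopolymers=4, n_strs=4, n_inherited_indels=6,
            n_denovo_indels=2, n_artifact_sites=3, coverage=8, seed=31,
        )
        a, b = run_simulation(cfg), run_simulation(cfg)
        assert a.reference == b.reference
        assert a.truth.sites.equals(b.truth.sites)
        for role in a.reads:
            ra = [(r.name, r.pos, r.cigar, r.seq) for r in a.reads[role]]
            rb = [(r.name, r.pos, r.cigar, r.seq) for r in b.reads[role]]
            assert ra == rb


class TestEndToEndSignal:
    def test_denovo_signature_at_planted_sites(self, sim):
        ref = sim.reference_map
        from dnmindel.features import extract_trio_features

        for site in sim.truth.denovo_sites():
            v = extract_trio_features(sim.reads, site, ref).values
            assert v["offspring_alt_fraction"] > 0.15
            assert v["father_alt_fraction"] < 0.1
            assert v["mother_alt_fraction"] < 0.1
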