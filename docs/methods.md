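# Methods

## Problem and approach

De novo indels — insertions/deletions present in a child but in neither
parent's germline — occur at roughly three events per genome, while trio
variant callers emit orders of magnitude more putative de novo indel calls,
most of them alignment or library artifacts concentrated in low-complexity
sequence. `dnmindel` is a post-hoc filter: it takes putative de novo indel
calls from any upstream caller, extracts pileup and sequence-context
features from the trio's alignments, and scores each candidate with a
gradient-boosted tree ensemble. The score is the model's probability in
[0, 1] that the call is a real de novo indel; candidates scoring below a
cutoff (default 0.4) are marked with a `dnm_low_score` FILTER entry.

Because experimentally validated de novo indels are far too scarce to train
on, positives are manufactured: at sites where one parent is heterozygous
for an indel and both the other parent and the offspring are homozygous
reference, the carrier parent's and the offspring's reads over the site are
exchanged. The exchanged site now shows het-indel evidence in the child and
none in either parent — the exact signature of a de novo event — while every
read retains authentic sequencing noise. Negatives are (a) putative de novo
calls minus any validated ones (almost all of which are false) and
(b) inherited indels (transmitted parent–child variation, i.e. real indel
signal that is *not* de novo).

## Feature set

Ten pileup metrics per family member (father, mother, offspring), plus
seven site-level features: 37 in total, in a fixed, fingerprinted order.

Per-sample metrics, computed from reads overlapping the anchor base after
excluding duplicates, secondary/supplementary alignments and mapping
quality < 20 (`min_mapq`, configurable):

| metric | definition |
|---|---|
| `depth` | filtered read count over the anchor |
| `alt_count` | reads whose alignment contains an indel of the candidate's type and length whose left-aligned position equals the candidate's |
| `alt_fraction` | `alt_count / depth` |
| `mean_mapq_all`, `mean_mapq_alt` | mean mapping quality of all / alt reads (phred) |
| `mean_baseq_flank` | mean base quality of the ≤5 read bases on each side of the anchor |
| `softclip_fraction` | fraction of reads with any soft-clipped segment |
| `fwd_alt_fraction` | fraction of alt reads on the forward strand |
| `mismatch_fraction` | fraction of reads with > 3 non-indel mismatches |
| `other_indel_count` | distinct non-candidate indel alleles left-aligned within 10 bp of the anchor |

Degenerate pileups use fixed imputation so vectors are always complete:
depth 0 ⇒ all means and fractions 0 with `fwd_alt_fraction` 0.5;
`alt_count` 0 ⇒ `mean_mapq_alt` 0 and `fwd_alt_fraction` 0.5 (0.5 is the
"no strand information" neutral value).

Site-level features: `indel_length`, `indel_type_code` (0 deletion /
1 insertion), and the five repeat-context values below.

The alt-support rule is deliberately strict — exact type, length and
left-aligned position. Nearby or different-length indels are evidence of
local noise, not of the candidate allele, and are tallied in
`other_indel_count` instead.

## Repeat context

Indel errors concentrate in homopolymers and short tandem repeats (STRs),
so the reference context of each candidate contributes two features:

* **homopolymer** — a perfect run of one base, counted when the tract
  reaches ≥ 4 copies (= 4 bases);
* **STR** — a perfect tandem repeat with a primitive unit of 2–6 bp and
  ≥ 3 complete copies.

"Tract" is counted in unit copies, which coincides with bases for
homopolymers and requires, e.g., ≥ 9 bases for a 3-bp unit. Units are
primitive (`AAAA` is a homopolymer only, never an `AA`×2 STR; `ACACAC`
reports unit `AC`, never `ACAC`), reported intervals contain complete
copies only and are maximal, and `N` breaks any tract.

A feature is flagged when a qualifying tract overlaps the closed window
±10 bp (`flank`, configurable) around the candidate's anchor. Left-aligned
indel placement inside a repeat is ambiguous, so a small symmetric window
is used rather than the anchor base alone. The homopolymer and STR features
are annotated independently of each other — they are separate model inputs
— and within each class the longest overlapping tract wins, ties going to
the smaller unit and then the leftmost start. Reported values:
`is_homopolymer`, `homopolymer_tract_length` (bases), `is_str`,
`str_unit_size`, `str_copy_count` (zeros when unflagged).

## Alignment exchange

Exchange-eligible sites are taken from a jointly-called trio VCF: exactly
one parent 0/1 for a biallelic indel, the other parent and the offspring
0/0; half-calls and multi-allelic records are excluded. For each site, all
reads overlapping `[anchor − 500 bp, anchor + 500 bp + indel_length)` move
to the other member, with their sample label rewritten. The 500-bp window
(configurable) comfortably exceeds a read length, so all indel evidence
transfers while side effects stay bounded. Only reads move; mate/flag
metadata of pairs straddling the window boundary is left as-is, an accepted
minor inconsistency since all features are pileup-local. Sites whose window
intersects an already-exchanged window are skipped (greedy, genomic order)
to prevent double-moving reads; sites with an empty donor window are
dropped with a warning. The exchange conserves the combined read multiset
and is an involution.

Alignments are consumed as given. If local-assembly realignment is wanted
(e.g. ABRA2), pass the realigned BAMs as the trio alignment inputs; the
package performs no realignment itself.

## Training table and model

Composition defaults mirror a 2000-positive / 4000-negative design: all
validated positives are always included (never down-sampled), plus 1970
synthetic positives and 2000 + 2000 false-de-novo and inherited negatives
drawn uniformly without replacement under a caller-supplied seed
(`numpy.random.default_rng`). The 1:2 class imbalance is passed to the
learner unweighted. Site identity is the normalized
(chrom, pos, ref, alt) key — all alleles are left-aligned and parsimonious
on ingest — and a site may appear in only one class. A
`split_by_chromosome` helper supports held-out-chromosome designs (e.g.
train on chr1–6, evaluate on chr7–22).

The learner is `sklearn.ensemble.GradientBoostingClassifier` with
defaults n_trees = 1000, learning_rate = 0.01, max_depth = 3,
subsample = 0.5, seeded — conventional slow-learning boosted-tree settings;
all exposed in `ModelSpec`. The emitted score is the raw predicted
probability of the positive class (no calibration). Filtering retains
`score ≥ cutoff`; the boundary is inclusive by convention and tested.
Models persist with joblib together with the feature-schema fingerprint
(sha-256 of the ordered feature names); prediction refuses a model whose
fingerprint differs from the extraction schema.

Diagnostics: feature importances are total impurity-reduction influences
normalized to sum 100, ties broken by name for determinism; PCA operates on
z-scored features (constant columns dropped with a log message) with
component signs fixed so each component's largest-magnitude loading is
positive.

## Simulator

The simulator generates everything the pipeline consumes, with exact truth:

* **Reference** — uniform random sequence (default one 200 kb chromosome)
  with non-overlapping planted homopolymers (tracts 4–15) and STRs
  (primitive units 2–6 bp, 3–10 copies). Flanking bases are forced to
  mismatch so planted tract lengths are exact.
* **Genotypes** — inherited indels are het in one random parent with random
  phase and transmitted by a fair coin; de novo indels (1–6 bp, 50/50
  ins/del) are het in the offspring only; all variant sites sit in
  non-repetitive background, spaced > read length apart. Artifact sites sit
  at planted repeat starts and carry no variant in any member.
* **Reads** — drawn uniformly along each haplotype to half the target
  coverage per haplotype (default 40× total), 100 bp, constant base quality
  35, MAPQ 60, random strand, substitution errors at 0.002/bp. Reads are
  emitted pre-aligned: coordinates and CIGARs come from the known
  haplotype-to-reference mapping, not an aligner, keeping tests hermetic
  and truth exact. At each artifact site, 10–30% of one random member's
  reads receive a 1–2 bp slippage indel (a deletion of repeat bases or a
  duplication of them), mimicking the repeat-region errors that dominate
  false de novo calls.

Outputs can be written as FASTA (+faidx), coordinate-sorted indexed BAM (or
SAM), trio genotype VCF, candidate VCF, PED and a truth TSV; everything is
byte-reproducible per seed.

What the simulator does **not** model: realistic quality-score
distributions, GC/coverage bias, mate-pair fragment geometry, mapping
ambiguity from genome-wide repeat homology, structural variants, or
CIGAR-representation noise from real aligners. Passing the end-to-end tests
therefore demonstrates that the machinery is correct and that the model
learns the intended signal under controlled conditions — not that the
shipped defaults reach any particular accuracy on real sequencing data,
where feature distributions are broader and artifacts more diverse.

## Evaluation experiment

`dnmindel.experiments.end_to_end_recovery` (also run by
`scripts/acceptance.py`) simulates two independent replicates of a 1 Mb,
40× trio carrying 30 planted de novo indels, 300 repeat-region artifact
candidates and 600 inherited het indels; trains on replicate 1 (planted de
novos as validated positives, exchange sites as synthetic positives,
artifacts and transmitted indels as negatives — ~870 examples) and scores
replicate 2's 330 candidates at cutoff 0.4, reporting sensitivity, artifact
removal and AUC. The 1 Mb/40× scale keeps a full run to a few minutes on
one core while leaving every rate estimated from hundreds of sites.

## Numerical and degenerate-input choices

* Coordinates: VCF 1-based anchors at the surface, 0-based half-open
  internally; insertions attach to the anchor base.
* Normalization failure (e.g. an allele inconsistent with the reference) or
  non-indel/multi-allelic records: skipped on ingest with a counted warning
  at prediction time (record conservation in the scored VCF is preserved —
  unscoreable records pass through unannotated).
* Repeat scanning around a site extends its window by an adaptively doubled
  pad so tracts reaching in from outside are never truncated.
* Single-class training tables, schema mismatches, out-of-range cutoffs and
  requests exceeding pool sizes are hard errors; all-zero feature
  importance (constant features) is a warning, not an error.
* Determinism: every stochastic step takes an explicit seed; rerunning
  `run-all` on identical inputs produces byte-identical model and VCF
  outputs (verified by checksum in the test suite).

## Known limitations

* The per-sample metric definitions are this package's own concrete feature
  set covering depth, allele balance, quality, strand, clipping and local
  noise; other filters choose different, partially overlapping sets.
* Mate information is not used; paired-end evidence (insert-size shifts,
  discordant pairs) is invisible to the features.
* The exchange transfers reads wholesale within a window; coverage
  differences between donor and recipient are inherited by the synthetic
  site.
* Scores are uncalibrated probabilities; the 0.4 default cutoff is a
  sensitivity/precision trade-off that users should tune to their callset.
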