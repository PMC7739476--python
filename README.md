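# dnmindel

Machine-learning filtering of de novo indel calls in parent–offspring trios.

De novo indels — insertions/deletions carried by a child but by neither
parent — arise at only ~3 events per genome, yet trio callers
(DeNovoGear, PhaseByTransmission, TrioDeNovo, naive genotype comparison …)
emit vastly more putative de novo indel calls than that, most of them
slippage and alignment artifacts concentrated in homopolymers and short
tandem repeats. `dnmindel` is a post-hoc filter for such callsets: it
extracts pileup and repeat-context features for each candidate from the
trio's alignments, scores the candidate with a gradient-boosted tree
ensemble, and removes calls scoring below a cutoff.

**Who it is for:** anyone with trio BAMs, a putative de novo indel VCF from
any upstream caller, and the wish to keep sensitivity while cutting the
false discovery rate.

## Method in brief

For a candidate indel at site *s* with trio alignments
(father, mother, offspring), the filter computes a 37-dimensional feature
vector **x**(*s*): ten pileup metrics per member (depth, indel-allele
support `alt_count`/`alt_fraction`, mapping and flanking base quality,
strand balance of alt reads, soft-clip fraction, mismatch noise, other
indel alleles at the site) plus indel length/type and the reference repeat
context — homopolymer (unit 1 bp, tract ≥ 4) and STR (primitive unit
2–6 bp, ≥ 3 copies) flags with tract sizes.

A gradient-boosting classifier *F* (1000 trees, depth 3, learning rate
0.01, subsample 0.5) is trained on labeled examples and emits
P(de novo | **x**) ∈ [0, 1]; calls with score < 0.4 (default) get a
`dnm_low_score` FILTER entry. Training data are assembled as:

* **positives** — experimentally validated de novo indels (all of them),
  plus *synthetic de novo indels*: at sites where one parent is 0/1 for an
  indel and the other parent and the child are 0/0, the carrier parent's
  and the child's reads over the site are exchanged, turning real inherited
  het evidence into a perfect de novo signature with authentic noise;
* **negatives** — putative de novo calls minus the validated ones (almost
  all false), and inherited indels (real, but not de novo).

A full synthetic-trio simulator (reference with planted repeats, Mendelian
genotypes with planted de novos, pre-aligned reads with errors and
repeat-slippage artifacts, complete truth tables) makes the whole pipeline
testable end to end without any external data. See `docs/methods.md` for
definitions, defaults and limitations.

## Worked example

Simulate a small ground-truthed trio, then train and predict in one go.
The simulated "putative de novo" callset contains the 8 planted true de
novos plus 25 repeat-region artifact candidates; the validated list plays
the role of a gold-standard de novo set.

```bash
dnmindel simulate --outdir sim --ref-length 100000 --n-homopolymers 25 \
    --n-strs 25 --n-inherited-indels 60 --n-denovo-indels 8 \
    --n-artifact-sites 25 --coverage 30 --seed 11

# validated list = the planted de novo sites (chrom/pos/ref/alt TSV)
awk -F'\t' 'NR==1{print "chrom\tpos\tref\talt"} \
    $8=="True"{print $1"\t"$2"\t"$3"\t"$4}' sim/truth_sites.tsv > validated.tsv

dnmindel run-all --reference sim/reference.fa --ped sim/trio.ped \
    --father-bam sim/FATHER.bam --mother-bam sim/MOTHER.bam \
    --offspring-bam sim/CHILD.bam --genotypes-vcf sim/trio_genotypes.vcf \
    --candidates-vcf sim/putative_denovo.vcf --validated-tsv validated.tsv \
    --outdir out --seed 7
```

which logs:

```
INFO dnmindel.pipeline: applied 22/31 alignment exchanges
INFO dnmindel.pipeline: training table composition: {'validated': 8, 'synthetic': 22, 'false_dnm': 25, 'inherited': 29}
INFO dnmindel.pipeline: retained 8, removed 25 of 33 candidates at cutoff 0.40
trained on 84 examples; scored 33 candidates; outputs in out
```

22 of 31 exchange-eligible sites were swapped (the rest had overlapping
swap windows), giving 30 positives and 54 negatives. All 33 candidates were
scored; the 8 retained calls are exactly the 8 planted true de novos —
e.g. from `out/scores.tsv`:

```
chrom   pos     ref     alt       score   retained
chr1    768     CCT     C         0.000856  0      <- artifact in a repeat
chr1    29861   AGACG   A         0.984291  1      <- planted de novo
chr1    30368   TG      T         0.995296  1      <- planted de novo
```

`out/scored.vcf` carries the same information as an INFO key
`DNMFILTER_SCORE` and a FILTER entry `dnm_low_score` on removed records.
On real data you would pass your own BAMs, the trio VCF from a joint
caller, your upstream de novo candidate VCF and whatever validated list you
have (it may be empty — then all non-synthetic positives are dropped and
candidates serve only as negatives).

A small packaged training table built from simulated data
(`dnmindel.training.load_demo_training_set()`) lets you try `train` /
`predict` without simulating first. Other subcommands: `annotate-repeats`,
`synthesize`, `extract`, `assemble` expose the individual pipeline stages.

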