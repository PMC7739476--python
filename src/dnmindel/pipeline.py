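"""End-to-end training and prediction pipelines.

Training: discover exchange-eligible sites in the trio genotype calls, swap
reads to manufacture synthetic de novo positives, extract features for the
positive and negative pools, assemble the labeled table and fit the
gradient-boosting model.  Prediction: extract features for every putative
de novo indel from an upstream caller, score with a trained model, and
write both a score TSV and a copy of the input VCF annotated with an INFO
key ``DNMFILTER_SCORE`` and a FILTER entry ``dnm_low_score`` below the
cutoff.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pysam
import yaml

import sklearn

from . import __version__
from .features import (
    DEFAULT_MIN_MAPQ,
    FEATURE_NAMES,
    TrioFeatureVector,
    extract_trio_features,
)
from .model import (
    DEFAULT_CUTOFF,
    ModelSpec,
    Prediction,
    TrainedModel,
    filter_calls,
    predict_scores,
    train_model,
)
from .reads import ReadSet, load_readset
from .repeats import DEFAULT_FLANK
from .synthesis import (
    DEFAULT_SWAP_WINDOW,
    apply_swaps,
    build_false_dnm_pool,
    find_swap_sites,
)
from .training import (
    DEFAULT_N_FALSE,
    DEFAULT_N_INHERITED,
    DEFAULT_N_SYNTHETIC,
    TrainingTable,
    assemble_training_set,
)
from .variants import (
    ROLES,
    CandidateIndel,
    Pedigree,
    read_candidates_tsv,
    read_candidates_vcf,
    read_pedigree,
    read_trio_genotypes,
)

logger = logging.getLogger(__name__)

SCORE_INFO_KEY = "DNMFILTER_SCORE"
LOW_SCORE_FILTER = "dnm_low_score"


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run (YAML-loadable)."""

    reference: str = ""
    father_bam: str = ""
    mother_bam: str = ""
    offspring_bam: str = ""
    pedigree: str = ""
    genotypes_vcf: str = ""  # jointly-called trio VCF (swap-site discovery + inherited negatives)
    candidates_vcf: str = ""  # putative de novo indels from an upstream caller
    validated_tsv: str = ""  # optional gold-standard de novo site list
    output_dir: str = "dnmindel_out"
    seed: int = 0
    cutoff: float = DEFAULT_CUTOFF
    min_mapq: int = DEFAULT_MIN_MAPQ
    repeat_flank: int = DEFAULT_FLANK
    swap_window: int = DEFAULT_SWAP_WINDOW
    max_swap_sites: int = 0  # 0 = no limit
    n_synthetic: int = DEFAULT_N_SYNTHETIC
    n_false: int = DEFAULT_N_FALSE
    n_inherited: int = DEFAULT_N_INHERITED
    model: ModelSpec = field(default_factory=ModelSpec)

    def __post_init__(self):
        if not (0.0 <= self.cutoff <= 1.0):
            raise ValueError(f"cutoff {self.cutoff} outside [0,1]")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        model = raw.pop("model", None)
        cfg = cls(**raw)
        if model:
            cfg.model = ModelSpec(**model)
        return cfg

    def validate_paths(self, training: bool) -> None:
        needed = ["reference", "father_bam", "mother_bam", "offspring_bam", "pedigree"]
        needed += ["genotypes_vcf"] if training else []
        needed += ["candidates_vcf"]
        for name in needed:
            p = getattr(self, name)
            if not p:
                raise ValueError(f"config field {name!r} is required but empty")
            if not Path(p).exists():
                raise FileNotFoundError(f"config field {name!r}: no such file {p}")


# ---------------------------------------------------------------------------
# shared plumbing


def load_reference(path: str) -> Mapping[str, str]:
    import pyfaidx

    return pyfaidx.Fasta(str(path), as_raw=False, sequence_always_upper=True)


def load_trio_readsets(config: PipelineConfig, pedigree: Pedigree) -> Dict[str, ReadSet]:
    return {
        role: load_readset(getattr(config, f"{role}_bam"), sample=getattr(pedigree, role))
        for role in ROLES
    }


def extract_features_for_sites(
    reads: Mapping[str, ReadSet],
    sites: Sequence[CandidateIndel],
    reference: Mapping[str, str],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    flank: int = DEFAULT_FLANK,
) -> List[TrioFeatureVector]:
    return [
        extract_trio_features(reads, s, reference, min_mapq=min_mapq, flank=flank)
        for s in sites
    ]


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _manifest(config: PipelineConfig, stage: str, inputs: Sequence[str]) -> Dict:
    return {
        "stage": stage,
        "tool_version": __version__,
        "sklearn_version": sklearn.__version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "schema": list(FEATURE_NAMES),
        "input_checksums": {p: _checksum(p) for p in inputs if p and Path(p).exists()},
    }


# ---------------------------------------------------------------------------
# training


def run_training_pipeline(config: PipelineConfig) -> Tuple[TrainedModel, TrainingTable]:
    """synthesize -> extract -> assemble -> train, writing all intermediates."""
    config.validate_paths(training=True)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference = load_reference(config.reference)
    pedigree = read_pedigree(config.pedigree)
    logger.info("trio: father=%s mother=%s offspring=%s",
                pedigree.father, pedigree.mother, pedigree.offspring)

    reads = load_trio_readsets(config, pedigree)
    genotypes = read_trio_genotypes(config.genotypes_vcf, pedigree, reference)
    candidates = read_candidates_vcf(config.candidates_vcf, reference)
    validated = (
        read_candidates_tsv(config.validated_tsv, reference) if config.validated_tsv else []
    )

    # synthetic positives by alignment exchange
    swaps = find_swap_sites(genotypes, window=config.swap_window)
    if config.max_swap_sites:
        swaps = swaps[: config.max_swap_sites]
    applied = apply_swaps(reads, swaps)
    logger.info("applied %d/%d alignment exchanges", len(applied), len(swaps))
    synthetic_sites = [s.site for s in applied]
    (out / "synthetic_sites.tsv").write_text(
        "chrom\tpos\tref\talt\tdonor_parent\n"
        + "".join(
            f"{s.site.chrom}\t{s.site.pos}\t{s.site.ref_allele}\t{s.site.alt_allele}\t{s.donor_parent}\n"
            for s in applied
        )
    )

    false_pool = build_false_dnm_pool(candidates, validated)
    inherited_sites = [
        g["site"]
        for g in genotypes
        if 1 in g["offspring"] and (1 in g["father"] or 1 in g["mother"])
    ]

    used = {s.key for s in synthetic_sites} | {s.key for s in validated}
    false_pool = [s for s in false_pool if s.key not in used]
    inherited_sites = [s for s in inherited_sites if s.key not in used and s.key not in {f.key for f in false_pool}]

    def feats(sites):
        return extract_features_for_sites(
            reads, sites, reference, min_mapq=config.min_mapq, flank=config.repeat_flank
        )

    table = assemble_training_set(
        validated=feats(validated),
        synthetic=feats(synthetic_sites),
        false_pool=feats(false_pool),
        inherited_pool=feats(inherited_sites),
        n_synthetic=min(config.n_synthetic, len(synthetic_sites)),
        n_false=min(config.n_false, len(false_pool)),
        n_inherited=min(config.n_inherited, len(inherited_sites)),
        seed=config.seed,
    )
    table.write(str(out / "training_set.tsv"), str(out / "training_composition.json"))
    logger.info("training table composition: %s", table.composition)

    model = train_model(table, config.model)
    model.save(str(out / "model.joblib"))
    manifest = _manifest(
        config, "training",
        [config.reference, config.father_bam, config.mother_bam,
         config.offspring_bam, config.genotypes_vcf, config.candidates_vcf],
    )
    manifest["composition"] = table.composition
    (out / "training_manifest.json").write_text(json.dumps(manifest, indent=2))
    return model, table


# ---------------------------------------------------------------------------
# prediction


def write_scored_vcf(
    in_vcf: str, out_vcf: str, scores: Mapping[Tuple, float], cutoff: float
) -> Tuple[int, int]:
    """Copy the candidate VCF, adding the score INFO key and the low-score
    FILTER; returns (n_retained, n_removed).  Records that could not be
    scored (malformed/non-indel) pass through unannotated."""
    n_ret = n_rem = 0
    with pysam.VariantFile(str(in_vcf)) as vin:
        header = vin.header.copy()
        header.add_line(
            f'##INFO=<ID={SCORE_INFO_KEY},Number=1,Type=Float,'
            'Description="De novo indel probability from the gradient boosting filter">'
        )
        header.add_line(
            f'##FILTER=<ID={LOW_SCORE_FILTER},Description='
            f'"Score below the de novo indel filter cutoff">'
        )
        with pysam.VariantFile(str(out_vcf), "w", header=header) as vout:
            for rec in vin:
                nrec = rec.copy()
                nrec.translate(header)
                if rec.alts and len(rec.alts) == 1:
                    key = (rec.chrom, rec.pos, rec.ref, rec.alts[0])
                    if key in scores:
                        s = scores[key]
                        nrec.info[SCORE_INFO_KEY] = float(s)
                        if s < cutoff:
                            nrec.filter.add(LOW_SCORE_FILTER)
                            n_rem += 1
                        else:
                            n_ret += 1
                vout.write(nrec)
    return n_ret, n_rem


def run_prediction_pipeline(
    config: PipelineConfig, model: TrainedModel
) -> List[Prediction]:
    """Score every well-formed candidate and write the score TSV, scored
    VCF and retained/removed site lists."""
    config.validate_paths(training=False)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference = load_reference(config.reference)
    pedigree = read_pedigree(config.pedigree)
    reads = load_trio_readsets(config, pedigree)

    # Read candidates, remembering each original record key so the scored
    # VCF can be annotated even when normalization moved the site.
    from .variants import _norm_or_none

    orig_to_norm: Dict[Tuple, Tuple] = {}
    candidates: List[CandidateIndel] = []
    seen = set()
    n_records = 0
    with pysam.VariantFile(config.candidates_vcf) as vcf:
        for rec in vcf:
            n_records += 1
            if rec.alts is None or len(rec.alts) != 1 or rec.alts[0] is None:
                continue
            if not rec.alts[0].isalpha() or len(rec.ref) == len(rec.alts[0]):
                continue
            cand = _norm_or_none(rec.chrom, rec.pos, rec.ref, rec.alts[0], reference)
            if cand is None:
                continue
            orig_to_norm[(rec.chrom, rec.pos, rec.ref, rec.alts[0])] = cand.key
            if cand.key in seen:
                logger.warning("duplicate candidate %s skipped", cand.key)
                continue
            seen.add(cand.key)
            candidates.append(cand)
    n_skipped = n_records - len(candidates)
    if n_skipped:
        logger.warning("%d VCF records were not scoreable biallelic indels", n_skipped)

    features = extract_features_for_sites(
        reads, candidates, reference, min_mapq=config.min_mapq, flank=config.repeat_flank
    )
    predictions = predict_scores(model, features)
    retained, removed = filter_calls(predictions, config.cutoff)
    logger.info("retained %d, removed %d of %d candidates at cutoff %.2f",
                len(retained), len(removed), len(predictions), config.cutoff)

    with open(out / "scores.tsv", "w") as fh:
        fh.write("chrom\tpos\tref\talt\tscore\tretained\n")
        for p in predictions:
            s = p.site
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.ref_allele}\t{s.alt_allele}\t"
                f"{p.score:.6f}\t{int(p.score >= config.cutoff)}\n"
            )
    for name, group in (("retained_sites.tsv", retained), ("removed_sites.tsv", removed)):
        with open(out / name, "w") as fh:
            fh.write("chrom\tpos\tref\talt\tscore\n")
            for p in group:
                s = p.site
                fh.write(f"{s.chrom}\t{s.pos}\t{s.ref_allele}\t{s.alt_allele}\t{p.score:.6f}\n")

    norm_scores = {p.site.key: p.score for p in predictions}
    score_map = {
        orig: norm_scores[norm]
        for orig, norm in orig_to_norm.items()
        if norm in norm_scores
    }
    write_scored_vcf(
        config.candidates_vcf, str(out / "scored.vcf"), score_map, config.cutoff
    )
    manifest = _manifest(
        config, "prediction",
        [config.reference, config.father_bam, config.mother_bam,
         config.offspring_bam, config.candidates_vcf],
    )
    manifest["n_candidates"] = len(predictions)
    manifest["n_retained"] = len(retained)
    (out / "prediction_manifest.json").write_text(json.dumps(manifest, indent=2))
    return predictions
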