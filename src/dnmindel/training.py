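"""Labeled training-table assembly with reproducible sampling.

Positives are the validated de novo indels (always all kept) plus a sampled
subset of the synthetic exchange sites; negatives are sampled false de novo
calls and inherited indels.  The default composition mirrors the 2000
positive / 4000 negative design: all validated examples, 1970 synthetic,
2000 false de novo and 2000 inherited.  Sampling is uniform without
replacement under a caller-supplied seed, so identical inputs and seed give
identical tables on any platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, TrioFeatureVector, schema_fingerprint

__all__ = [
    "LabeledExample",
    "TrainingTable",
    "assemble_training_set",
    "split_by_chromosome",
    "DEFAULT_N_SYNTHETIC",
    "DEFAULT_N_FALSE",
    "DEFAULT_N_INHERITED",
]

DEFAULT_N_SYNTHETIC = 1970
DEFAULT_N_FALSE = 2000
DEFAULT_N_INHERITED = 2000

SOURCES = ("validated", "synthetic", "false_dnm", "inherited")
POSITIVE_SOURCES = ("validated", "synthetic")


@dataclass(frozen=True)
class LabeledExample:
    """One feature vector with its class label and provenance."""

    features: TrioFeatureVector
    label: int
    source: str

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        expected = 1 if self.source in POSITIVE_SOURCES else 0
        if self.label != expected:
            raise ValueError(
                f"source {self.source!r} must carry label {expected}, got {self.label}"
            )


@dataclass
class TrainingTable:
    """Feature matrix + labels + provenance, with composition metadata.

    ``df`` has columns chrom/pos/ref/alt, the fixed feature schema, then
    ``label`` and ``source``.
    """

    df: pd.DataFrame
    fingerprint: str
    composition: Dict[str, int]
    seed: int

    def __post_init__(self):
        if self.df.duplicated(["chrom", "pos", "ref", "alt"]).any():
            dup = self.df[self.df.duplicated(["chrom", "pos", "ref", "alt"], keep=False)]
            raise ValueError(f"duplicate sites in training table:\n{dup[['chrom','pos','ref','alt','source']]}")
        if sum(self.composition.values()) != len(self.df):
            raise ValueError("composition counts do not sum to table size")
        bad = self.df[
            (self.df.source.isin(POSITIVE_SOURCES)) != (self.df.label == 1)
        ]
        if len(bad):
            raise ValueError("label/source consistency violated")

    @property
    def features(self) -> np.ndarray:
        return self.df[list(FEATURE_NAMES)].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return self.df["label"].to_numpy(dtype=int)

    def write(self, tsv_path: str, sidecar_path: str = None) -> None:
        self.df.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
        if sidecar_path:
            with open(sidecar_path, "w") as fh:
                json.dump(
                    {
                        "composition": self.composition,
                        "fingerprint": self.fingerprint,
                        "seed": self.seed,
                        "n_examples": len(self.df),
                    },
                    fh,
                    indent=2,
                )

    @classmethod
    def read(cls, tsv_path: str, seed: int = -1) -> "TrainingTable":
        df = pd.read_csv(tsv_path, sep="\t")
        missing = [c for c in FEATURE_NAMES if c not in df.columns]
        if missing:
            raise ValueError(f"training TSV lacks feature columns: {missing[:5]}...")
        comp = df["source"].value_counts().to_dict()
        return cls(df=df, fingerprint=schema_fingerprint(), composition=comp, seed=seed)


def load_demo_training_set() -> TrainingTable:
    """The packaged demo training table.

    A small labeled table assembled from one simulated trio (entirely
    synthetic data), shipped so that ``train`` and ``predict`` can be tried
    without running a simulation first.
    """
    from importlib.resources import files

    path = files("dnmindel").joinpath("data/demo_training_set.synthetic.tsv")
    with path.open("r") as fh:  # type: ignore[call-arg]
        df = pd.read_csv(fh, sep="\t")
    comp = df["source"].value_counts().to_dict()
    return TrainingTable(df=df, fingerprint=schema_fingerprint(), composition=comp, seed=404)


def _examples_to_frame(examples: Sequence[LabeledExample]) -> pd.DataFrame:
    rows = []
    for ex in examples:
        s = ex.features.site
        row = {"chrom": s.chrom, "pos": s.pos, "ref": s.ref_allele, "alt": s.alt_allele}
        row.update(ex.features.values)
        row["label"] = ex.label
        row["source"] = ex.source
        rows.append(row)
    cols = ["chrom", "pos", "ref", "alt", *FEATURE_NAMES, "label", "source"]
    return pd.DataFrame(rows, columns=cols)


def _sample(pool: Sequence, n: int, name: str, rng: np.random.Generator) -> List:
    if n > len(pool):
        raise ValueError(
            f"requested {n} examples from pool {name!r} but only {len(pool)} available"
        )
    idx = np.sort(rng.choice(len(pool), size=n, replace=False))
    return [pool[int(i)] for i in idx]


def assemble_training_set(
    validated: Sequence[TrioFeatureVector],
    synthetic: Sequence[TrioFeatureVector],
    false_pool: Sequence[TrioFeatureVector],
    inherited_pool: Sequence[TrioFeatureVector],
    n_synthetic: int = DEFAULT_N_SYNTHETIC,
    n_false: int = DEFAULT_N_FALSE,
    n_inherited: int = DEFAULT_N_INHERITED,
    seed: int = 0,
) -> TrainingTable:
    """Build the labeled table: every validated positive, plus seeded
    uniform samples (without replacement) of the synthetic positives and the
    two negative pools.  A site appearing in more than one class is a
    construction error and is rejected."""
    rng = np.random.default_rng(seed)
    chosen = (
        [LabeledExample(f, 1, "validated") for f in validated]
        + [LabeledExample(f, 1, "synthetic") for f in _sample(synthetic, n_synthetic, "synthetic", rng)]
        + [LabeledExample(f, 0, "false_dnm") for f in _sample(false_pool, n_false, "false_dnm", rng)]
        + [LabeledExample(f, 0, "inherited") for f in _sample(inherited_pool, n_inherited, "inherited", rng)]
    )
    seen: Dict[Tuple, str] = {}
    for ex in chosen:
        key = ex.features.site.key
        if key in seen:
            raise ValueError(
                f"site {key} appears in both {seen[key]!r} and {ex.source!r}"
            )
        seen[key] = ex.source
    composition = {s: sum(1 for ex in chosen if ex.source == s) for s in SOURCES}
    return TrainingTable(
        df=_examples_to_frame(chosen),
        fingerprint=schema_fingerprint(),
        composition=composition,
        seed=seed,
    )


def split_by_chromosome(
    examples: pd.DataFrame,
    train_chroms: Iterable[str],
    eval_chroms: Iterable[str],
    on_unassigned: str = "reject",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Partition example rows by chromosome into training and evaluation
    sets (e.g. chr1-6 for training, chr7-22 for evaluation).

    ``on_unassigned`` controls rows on chromosomes in neither set:
    ``"reject"`` raises, ``"drop"`` discards them with a log message.
    """
    train_set: Set[str] = set(train_chroms)
    eval_set: Set[str] = set(eval_chroms)
    if train_set & eval_set:
        raise ValueError(f"train/eval chromosome sets overlap: {sorted(train_set & eval_set)}")
    in_train = examples["chrom"].isin(train_set)
    in_eval = examples["chrom"].isin(eval_set)
    orphan = ~(in_train | in_eval)
    if orphan.any():
        if on_unassigned == "reject":
            raise ValueError(
                f"{int(orphan.sum())} examples on chromosomes outside both sets: "
                f"{sorted(examples.loc[orphan, 'chrom'].unique())}"
            )
        import logging

        logging.getLogger(__name__).info(
            "dropping %d examples on unassigned chromosomes", int(orphan.sum())
        )
    return examples[in_train].copy(), examples[in_eval].copy()
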