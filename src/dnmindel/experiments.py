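"""Self-contained evaluation experiments on simulated trios.

The headline experiment trains the filter on one simulated trio replicate
and measures recovery on an independent replicate: how many planted true
de novo indels survive the score cutoff and how many repeat-region artifact
candidates are removed.  It exercises the complete pipeline — simulation,
alignment exchange, feature extraction, training-set assembly, model
fitting, scoring and filtering — with no external inputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score

from .features import extract_trio_features
from .model import (
    DEFAULT_CUTOFF,
    ModelSpec,
    TrainedModel,
    filter_calls,
    predict_scores,
    train_model,
)
from .simulate import SimConfig, TrioSimulation, run_simulation
from .synthesis import apply_swaps, find_swap_sites
from .training import TrainingTable, assemble_training_set

__all__ = ["RecoveryResult", "build_training_table", "end_to_end_recovery"]

# Conditions of the two-replicate recovery experiment: a 1 Mb single
# chromosome at 40x trio coverage carrying 30 planted de novo indels and 300
# repeat-region artifact candidates, with enough inherited het indels to
# feed both the alignment-exchange positives and the inherited negatives.
RECOVERY_CONFIG = dict(
    ref_length=1_000_000,
    n_homopolymers=170,
    n_strs=160,
    n_inherited_indels=600,
    n_denovo_indels=30,
    n_artifact_sites=300,
    coverage=40.0,
    read_length=100,
    base_error_rate=0.002,
)

_REPLICATE_OFFSET = 1_000_003  # seed-splits the two replicates


@dataclass
class RecoveryResult:
    """Outcome of the two-replicate recovery experiment."""

    n_true: int
    n_true_retained: int
    n_artifacts: int
    n_artifacts_removed: int
    auc: float
    cutoff: float
    composition: Dict[str, int]
    true_scores: List[float]
    artifact_scores: List[float]

    @property
    def sensitivity(self) -> float:
        return self.n_true_retained / self.n_true

    @property
    def artifact_removal_rate(self) -> float:
        return self.n_artifacts_removed / self.n_artifacts


def build_training_table(sim: TrioSimulation, seed: int) -> TrainingTable:
    """Assemble a labeled table from one simulated trio: planted de novos as
    validated positives, alignment-exchange sites as synthetic positives,
    artifact candidates as false de novos and transmitted indels as
    inherited negatives.  The exchange mutates ``sim``'s read sets."""
    reference = sim.reference_map
    swaps = find_swap_sites(sim.truth.genotype_records())
    applied = apply_swaps(sim.reads, swaps)

    def feats(sites):
        return [extract_trio_features(sim.reads, s, reference) for s in sites]

    synthetic = feats([s.site for s in applied])
    validated = feats(sim.truth.denovo_sites())
    false_pool = feats(sim.truth.artifact_sites())
    inherited = feats(sim.truth.inherited_sites())
    return assemble_training_set(
        validated,
        synthetic,
        false_pool,
        inherited,
        n_synthetic=len(synthetic),
        n_false=len(false_pool),
        n_inherited=len(inherited),
        seed=seed,
    )


def end_to_end_recovery(
    seed: int = 1,
    cutoff: float = DEFAULT_CUTOFF,
    model_spec: Optional[ModelSpec] = None,
    config_overrides: Optional[dict] = None,
) -> RecoveryResult:
    """Train on replicate 1, score replicate 2, filter at ``cutoff``.

    The two replicates share their study conditions but are simulated from
    split seeds, so the evaluation trio is fully independent of the
    training trio.
    """
    conditions = dict(RECOVERY_CONFIG)
    if config_overrides:
        conditions.update(config_overrides)
    spec = model_spec or ModelSpec(seed=seed)

    sim1 = run_simulation(SimConfig(seed=seed, **conditions))
    table = build_training_table(sim1, seed=seed)
    model = train_model(table, spec)
    composition = dict(table.composition)
    del sim1, table  # free the training replicate before simulating the next

    sim2 = run_simulation(SimConfig(seed=seed + _REPLICATE_OFFSET, **conditions))
    reference = sim2.reference_map
    true_sites = sim2.truth.denovo_sites()
    artifact_sites = sim2.truth.artifact_sites()
    features = [
        extract_trio_features(sim2.reads, s, reference)
        for s in true_sites + artifact_sites
    ]
    predictions = predict_scores(model, features)
    true_scores = [p.score for p in predictions[: len(true_sites)]]
    artifact_scores = [p.score for p in predictions[len(true_sites) :]]
    retained, _ = filter_calls(predictions, cutoff)
    retained_keys = {p.site.key for p in retained}

    labels = [1] * len(true_scores) + [0] * len(artifact_scores)
    return RecoveryResult(
        n_true=len(true_sites),
        n_true_retained=sum(1 for s in true_sites if s.key in retained_keys),
        n_artifacts=len(artifact_sites),
        n_artifacts_removed=sum(1 for s in artifact_sites if s.key not in retained_keys),
        auc=float(roc_auc_score(labels, true_scores + artifact_scores)),
        cutoff=cutoff,
        composition=composition,
        true_scores=true_scores,
        artifact_scores=artifact_scores,
    )
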