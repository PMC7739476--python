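"""Gradient-boosting classifier: training, scoring, filtering, diagnostics.

A boosted ensemble of shallow regression trees is fit to the labeled
training table and emits, for each candidate site, the probability in
[0, 1] of being a real de novo indel; candidates scoring below the cutoff
(default 0.4) are filtered out.  Feature importances (total
impurity-reduction influence, normalized to sum 100, the convention of
boosted-tree packages) and a PCA projection of the standardized training
features are provided as diagnostics of what the model learned and how
separable the classes are.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import joblib
import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import GradientBoostingClassifier

from .features import FEATURE_NAMES, TrioFeatureVector, schema_fingerprint
from .training import TrainingTable
from .variants import CandidateIndel

__all__ = [
    "ModelSpec",
    "TrainedModel",
    "Prediction",
    "train_model",
    "predict_scores",
    "filter_calls",
    "rank_feature_importance",
    "pca_project",
    "DEFAULT_CUTOFF",
]

DEFAULT_CUTOFF = 0.4


@dataclass(frozen=True)
class ModelSpec:
    """Boosting hyperparameters."""

    n_trees: int = 1000
    learning_rate: float = 0.01
    max_depth: int = 3
    subsample_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if not (0 < self.subsample_fraction <= 1):
            raise ValueError("subsample_fraction must be in (0, 1]")


@dataclass(frozen=True)
class Prediction:
    site: CandidateIndel
    score: float

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0,1]")


@dataclass
class TrainedModel:
    """Fitted ensemble plus the schema fingerprint it was trained under."""

    estimator: GradientBoostingClassifier
    fingerprint: str
    spec: ModelSpec
    composition: Dict[str, int]
    feature_names: Tuple[str, ...] = tuple(FEATURE_NAMES)

    def save(self, path: str) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        obj = joblib.load(path)
        if not isinstance(obj, cls):
            raise TypeError(f"{path} does not contain a TrainedModel")
        return obj

    def check_schema(self, fingerprint: str) -> None:
        if fingerprint != self.fingerprint:
            raise ValueError(
                f"feature schema fingerprint {fingerprint} does not match the "
                f"model's training schema {self.fingerprint}; feature names or "
                "order differ between training and prediction"
            )


def train_model(table: TrainingTable, spec: ModelSpec = ModelSpec()) -> TrainedModel:
    """Fit the boosted ensemble on a two-class training table.

    Deterministic given ``spec.seed``; class imbalance is passed through
    unweighted.
    """
    y = table.labels
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(f"training table contains a single class ({classes.tolist()}); need both")
    x = table.features
    if np.isnan(x).any():
        raise ValueError("training features contain missing values")
    est = GradientBoostingClassifier(
        n_estimators=spec.n_trees,
        learning_rate=spec.learning_rate,
        max_depth=spec.max_depth,
        subsample=spec.subsample_fraction,
        random_state=spec.seed,
    )
    est.fit(x, y)
    return TrainedModel(
        estimator=est,
        fingerprint=table.fingerprint,
        spec=spec,
        composition=dict(table.composition),
    )


def predict_scores(
    model: TrainedModel, features: Sequence[TrioFeatureVector]
) -> List[Prediction]:
    """Score each candidate in [0, 1]; order-preserving and deterministic."""
    model.check_schema(schema_fingerprint())
    if not features:
        return []
    x = np.array([f.as_row() for f in features], dtype=float)
    scores = model.estimator.predict_proba(x)[:, 1]
    scores = np.clip(scores, 0.0, 1.0)
    return [Prediction(site=f.site, score=float(s)) for f, s in zip(features, scores)]


def filter_calls(
    predictions: Sequence[Prediction], cutoff: float = DEFAULT_CUTOFF
) -> Tuple[List[Prediction], List[Prediction]]:
    """Partition predictions into (retained, removed) at the score cutoff;
    a score exactly equal to the cutoff is retained."""
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError(f"cutoff {cutoff} outside [0,1]")
    retained = [p for p in predictions if p.score >= cutoff]
    removed = [p for p in predictions if p.score < cutoff]
    return retained, removed


def rank_feature_importance(model: TrainedModel) -> List[Tuple[str, float]]:
    """Relative influence of each feature, normalized to sum 100 and sorted
    descending (ties broken by feature name)."""
    imp = np.asarray(model.estimator.feature_importances_, dtype=float)
    total = imp.sum()
    if total <= 0:
        import logging

        logging.getLogger(__name__).warning(
            "model has all-zero feature importances (constant features?)"
        )
        rel = np.zeros_like(imp)
    else:
        rel = imp / total * 100.0
    pairs = list(zip(model.feature_names, rel.tolist()))
    pairs.sort(key=lambda kv: (-kv[1], kv[0]))
    return pairs


def pca_project(
    table, n_components: int = 3
) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """PCA of the standardized training features.

    Accepts a :class:`TrainingTable` or a bare feature matrix.  Features are
    z-scored (sample s.d.); constant features are dropped with a log
    message.  Component signs follow the convention that each component's
    largest-magnitude loading is positive.  Returns
    (coordinates, explained-variance fractions, names of features used).
    """
    if isinstance(table, TrainingTable):
        x = table.features
        names = list(FEATURE_NAMES)
    else:
        x = np.asarray(table, dtype=float)
        names = [f"f{i}" for i in range(x.shape[1])]
    if n_components > x.shape[1]:
        raise ValueError(f"n_components {n_components} exceeds {x.shape[1]} features")
    if x.shape[0] < n_components:
        raise ValueError(f"fewer examples ({x.shape[0]}) than components ({n_components})")
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        import logging

        dropped = [n for n, k in zip(names, keep) if not k]
        logging.getLogger(__name__).info("dropping %d constant features: %s", len(dropped), dropped[:8])
    names_used = [n for n, k in zip(names, keep) if k]
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(z)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(n_components):
        i = int(np.argmax(np.abs(pca.components_[j])))
        if pca.components_[j, i] < 0:
            pca.components_[j] = -pca.components_[j]
            coords[:, j] = -coords[:, j]
    return coords, pca.explained_variance_ratio_.copy(), names_used
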