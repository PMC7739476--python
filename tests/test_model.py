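"""Classifier training, scoring, filtering, importance and PCA diagnostics."""

import numpy as np
import pandas as pd
import pytest

from dnmindel.features import FEATURE_NAMES, TrioFeatureVector, schema_fingerprint
from dnmindel.model import (
    ModelSpec,
    Prediction,
    TrainedModel,
    filter_calls,
    pca_project,
    predict_scores,
    rank_feature_importance,
    train_model,
)
from dnmindel.training import TrainingTable
from dnmindel.variants import CandidateIndel
from oracles import brute_force_pca, rank_auc


def make_table(n_pos=60, n_neg=120, seed=0, informative=("offspring_alt_fraction",)):
    """Separable synthetic table: positives high in the informative
    features, negatives low, everything else noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_pos + n_neg):
        pos = i < n_pos
        vals = {k: float(rng.normal(0, 0.05)) for k in FEATURE_NAMES}
        for k in informative:
            vals[k] = float(np.clip(rng.normal(0.4 if pos else 0.02, 0.05), 0, 1))
        row = {"chrom": "chr1", "pos": 100 + 11 * i, "ref": "AT", "alt": "A"}
        row.update(vals)
        row["label"] = int(pos)
        row["source"] = "validated" if pos else "false_dnm"
        rows.append(row)
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", *FEATURE_NAMES, "label", "source"])
    comp = {"validated": n_pos, "false_dnm": n_neg}
    return TrainingTable(df=df, fingerprint=schema_fingerprint(), composition=comp, seed=seed)


def vectors_from_table(table):
    out = []
    for r in table.df.itertuples(index=False):
        d = r._asdict()
        site = CandidateIndel(d["chrom"], int(d["pos"]), d["ref"], d["alt"])
        out.append(TrioFeatureVector(site=site, values={k: d[k] for k in FEATURE_NAMES}))
    return out


SPEC = ModelSpec(n_trees=120, seed=0)


@pytest.fixture(scope="module")
def fitted():
    table = make_table()
    return table, train_model(table, SPEC)


class TestTraining:
    def test_separable_table_training_auc_above_099(self, fitted):
        table, model = fitted
        preds = predict_scores(model, vectors_from_table(table))
        pos = [p.score for p, y in zip(preds, table.labels) if y == 1]
        neg = [p.score for p, y in zip(preds, table.labels) if y == 0]
        assert rank_auc(pos, neg) > 0.99

    def test_single_class_rejected(self):
        table = make_table(n_pos=0, n_neg=30)
        with pytest.raises(ValueError, match="single class"):
            train_model(table, SPEC)

    def test_save_load_round_trip_scores_identical(self, fitted, tmp_path):
        table, model = fitted
        vecs = vectors_from_table(table)[:40]
        before = [p.score for p in predict_scores(model, vecs)]
        model.save(str(tmp_path / "m.joblib"))
        loaded = TrainedModel.load(str(tmp_path / "m.joblib"))
        after = [p.score for p in predict_scores(loaded, vecs)]
        assert before == after

    def test_deterministic_given_seed(self):
        table = make_table()
        m1 = train_model(table, SPEC)
        m2 = train_model(table, SPEC)
        vecs = vectors_from_table(table)[:20]
        assert [p.score for p in predict_scores(m1, vecs)] == [
            p.score for p in predict_scores(m2, vecs)
        ]


class TestPrediction:
    def test_scores_bounded_and_order_preserved(self, fitted):
        table, model = fitted
        vecs = vectors_from_table(table)
        preds = predict_scores(model, vecs)
        assert all(0.0 <= p.score <= 1.0 for p in preds)
        assert [p.site for p in preds] == [v.site for v in vecs]

    def test_empty_batch(self, fitted):
        _, model = fitted
        assert predict_scores(model, []) == []

    def test_permutation_equivariance(self, fitted):
        table, model = fitted
        vecs = vectors_from_table(table)[:30]
        fwd = {p.site.key: p.score for p in predict_scores(model, vecs)}
        rev = {p.site.key: p.score for p in predict_scores(model, vecs[::-1])}
        assert fwd == rev

    def test_schema_mismatch_rejected(self, fitted):
        _, model = fitted
        model.fingerprint = "0" * 16
        try:
            with pytest.raises(ValueError, match="fingerprint"):
                predict_scores(model, [])
        finally:
            model.fingerprint = schema_fingerprint()


def pred(score, pos=100):
    return Prediction(CandidateIndel("chr1", pos, "AT", "A"), score)


class TestFilter:
    def test_boundary_score_retained_at_cutoff(self):
        preds = [pred(0.39, 10), pred(0.40, 20), pred(0.41, 30)]
        retained, removed = filter_calls(preds, 0.4)
        assert [p.score for p in retained] == [0.40, 0.41]
        assert [p.score for p in removed] == [0.39]

    def test_extreme_cutoffs(self):
        preds = [pred(0.1, 10), pred(0.9, 20)]
        assert len(filter_calls(preds, 0.0)[0]) == 2
        assert len(filter_calls(preds, 1.0)[0]) == 0

    def test_cutoff_monotonic_nesting(self):
        rng = np.random.default_rng(3)
        preds = [pred(float(s), 10 + 7 * i) for i, s in enumerate(rng.random(50))]
        prev = None
        for c in (0.1, 0.3, 0.5, 0.8):
            cur = {p.site.key for p in filter_calls(preds, c)[0]}
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            filter_calls([], 1.5)

    def test_score_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="score"):
            pred(1.2)


class TestImportance:
    def test_influences_sum_to_100_sorted_descending(self, fitted):
        _, model = fitted
        ranks = rank_feature_importance(model)
        vals = [v for _, v in ranks]
        assert sum(vals) == pytest.approx(100.0, abs=1e-6)
        assert vals == sorted(vals, reverse=True)
        assert all(v >= 0 for v in vals)

    def test_single_informative_feature_ranks_first(self, fitted):
        _, model = fitted
        assert rank_feature_importance(model)[0][0] == "offspring_alt_fraction"

    def test_constant_features_warn_with_zero_influence(self, caplog):
        table = make_table(n_pos=10, n_neg=10)
        for k in FEATURE_NAMES:
            table.df[k] = 1.0
        model = train_model(table, ModelSpec(n_trees=10, seed=0))
        with caplog.at_level("WARNING"):
            ranks = rank_feature_importance(model)
        assert sum(v for _, v in ranks) == 0.0
        assert "zero" in caplog.text


class TestPCA:
    def test_matches_brute_force_eigendecomposition(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(20, 5))
        coords, frac, _ = pca_project(x, n_components=3)
        o_coords, o_frac = brute_force_pca(x, 3)
        np.testing.assert_allclose(coords, o_coords, atol=1e-8)
        np.testing.assert_allclose(frac, o_frac, atol=1e-10)

    def test_explained_variance_nonincreasing_and_bounded(self):
        rng = np.random.default_rng(5)
        _, frac, _ = pca_project(rng.normal(size=(40, 6)), 4)
        assert (np.diff(frac) <= 1e-12).all() and frac.sum() <= 1 + 1e-9

    def test_rank_one_data_first_component_explains_all(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=(30, 1))
        x = base @ rng.normal(size=(1, 4))
        _, frac, _ = pca_project(x, 2)
        assert frac[0] == pytest.approx(1.0)

    def test_three_components_on_training_table(self, fitted):
        table, _ = fitted
        coords, frac, used = pca_project(table, n_components=3)
        assert coords.shape == (len(table.df), 3)
        assert len(frac) == 3

    def test_fewer_examples_than_components_rejected(self):
        with pytest.raises(ValueError, match="fewer examples"):
            pca_project(np.zeros((2, 5)) + np.arange(5), 3)
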