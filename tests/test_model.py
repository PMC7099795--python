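"""Training, negative sampling, the CV protocol and case-study hygiene."""

import numpy as np
import pytest

from rflda.features import SampleMatrix, build_sample_matrix
from rflda.importance import ForestParams
from rflda.model import (
    RFLDA,
    case_study,
    cross_validate,
    partition_folds,
    sample_negatives,
    train_score,
)

FAST = ForestParams(n_trees=30, seed=0)


class TestNegativeSampling:
    def test_forced_sample(self):
        universe = [("l1", "d1"), ("l1", "d2"), ("l2", "d1"), ("l2", "d2")]
        positives = [("l1", "d1"), ("l2", "d2")]
        negs = sample_negatives(positives, universe, 2, seed=0)
        assert sorted(negs) == [("l1", "d2"), ("l2", "d1")]

    def test_reproducible_and_disjoint(self, small_matrices):
        positives = small_matrices.ld.pairs()
        universe = small_matrices.all_pairs()
        a = sample_negatives(positives, universe, len(positives), seed=42)
        b = sample_negatives(positives, universe, len(positives), seed=42)
        assert a == b
        assert not set(a) & set(positives)
        assert len(set(a)) == len(positives)
        c = sample_negatives(positives, universe, len(positives), seed=43)
        assert a != c

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError):
            sample_negatives([("l", "d")], [("l", "d")], 1, seed=0)


class TestFolds:
    def test_reference_positive_count_splits_540_539(self):
        rng = np.random.default_rng(0)
        parts = partition_folds(2697, 5, rng)
        assert sorted(len(p) for p in parts) == [539, 539, 539, 540, 540]

    def test_partition_is_disjoint_and_complete(self):
        rng = np.random.default_rng(1)
        parts = partition_folds(100, 7, rng)
        combined = np.concatenate(parts)
        assert sorted(combined.tolist()) == list(range(100))


class TestTrainScore:
    def _samples(self, X, y=None):
        return SampleMatrix(
            tuple(("l", f"d{i}") for i in range(len(X))),
            tuple(f"f{i}" for i in range(X.shape[1])),
            X,
            labels=None if y is None else y,
        )

    def test_memorizes_training_positive(self):
        rng = np.random.default_rng(0)
        X = rng.random((60, 5))
        y = (X[:, 0] > 0.5).astype(float)
        train = self._samples(X, y)
        test = self._samples(X[y == 1][:3])
        scores = train_score(train, test, ForestParams(n_trees=200, seed=0))
        assert (scores > 0.9).all()

    def test_constant_features_score_label_mean(self):
        X = np.full((40, 3), 0.5)
        y = np.r_[np.ones(10), np.zeros(30)]
        scores = train_score(
            self._samples(X, y), self._samples(X[:5]), ForestParams(n_trees=200, seed=1)
        )
        # every tree predicts its bootstrap label mean, so all test scores
        # are identical and the forest average sits near the label mean
        assert np.unique(scores).size == 1
        assert scores[0] == pytest.approx(0.25, abs=0.05)

    def test_feature_mismatch_rejected(self):
        X = np.random.default_rng(0).random((10, 2))
        train = self._samples(X, np.r_[np.ones(5), np.zeros(5)])
        test = SampleMatrix((("l", "d"),), ("other",), np.array([[0.1]]))
        with pytest.raises(ValueError):
            train_score(train, test, FAST)

    def test_scores_within_unit_interval_and_deterministic(self, small_matrices):
        positives = small_matrices.ld.pairs()
        negatives = sample_negatives(
            positives, small_matrices.all_pairs(), len(positives), seed=5
        )
        labels = np.r_[np.ones(len(positives)), np.zeros(len(negatives))]
        train = build_sample_matrix(positives + negatives, small_matrices, labels)
        test = build_sample_matrix(small_matrices.all_pairs()[:20], small_matrices)
        s1 = train_score(train, test, FAST)
        s2 = train_score(train, test, FAST)
        np.testing.assert_array_equal(s1, s2)
        assert (s1 >= 0.0).all() and (s1 <= 1.0).all()


class TestCrossValidate:
    def test_partition_and_metadata(self, small_matrices):
        cv = cross_validate(
            small_matrices, folds=3, repetitions=2, params=FAST, seed=3
        )
        assert cv.auc.shape == (2, 3)
        assert ((cv.auc >= 0) & (cv.auc <= 1)).all()
        assert ((cv.aupr >= 0) & (cv.aupr <= 1)).all()
        assert cv.metadata["folds"] == 3
        assert cv.metadata["mode"] == "heldout_positives"
        frame = cv.to_frame()
        assert len(frame) == 6

    def test_signal_beats_shuffled_null(self, small_matrices):
        cv = cross_validate(
            small_matrices, folds=3, repetitions=1, params=FAST, seed=4
        )
        null = cross_validate(
            small_matrices,
            folds=3,
            repetitions=1,
            params=FAST,
            seed=4,
            shuffle_labels=True,
        )
        assert cv.mean_auc > null.mean_auc + 0.15
        assert 0.3 < null.mean_auc < 0.7

    def test_literal_mode_readmits_trained_negatives(self, small_matrices):
        literal = cross_validate(
            small_matrices,
            folds=3,
            repetitions=1,
            params=FAST,
            seed=5,
            include_trained_negatives=True,
        )
        assert literal.metadata["include_trained_negatives"] is True

    def test_paper_exact_normalization_mode_runs(self, small_matrices):
        cv = cross_validate(
            small_matrices,
            folds=2,
            repetitions=1,
            params=FAST,
            seed=6,
            normalization="paper_exact",
        )
        assert cv.auc.shape == (1, 2)


class TestCaseStudy:
    def test_masking_hygiene(self, small_matrices):
        """No LD-derived feature of any sample carries an association of
        the investigated disease after hold-out masking."""
        disease = small_matrices.diseases[0]
        from rflda.io import AssociationMatrix
        from rflda.features import FeatureMatrices, feature_names
        from rflda.similarity import lncrna_similarity_matrix

        d_idx = small_matrices.ld.col_index(disease)
        masked_values = small_matrices.ld.values.copy()
        masked_values[:, d_idx] = 0
        ld_masked = AssociationMatrix(
            small_matrices.ld.row_ids, small_matrices.ld.col_ids, masked_values
        )
        masked = FeatureMatrices(
            ll=lncrna_similarity_matrix(ld_masked, small_matrices.dd),
            ld=ld_masked,
            lm=small_matrices.lm,
            dd=small_matrices.dd,
            md=small_matrices.md,
        )
        sm = build_sample_matrix(masked.all_pairs(), masked)
        names = sm.feature_ids
        col = names.index(f"LD-row:{disease}")
        assert (sm.values[:, col] == 0).all()
        rows = [i for i, (_, d) in enumerate(sm.pair_ids) if d == disease]
        ld_col_block = [i for i, n in enumerate(names) if n.startswith("LD-col:")]
        assert (sm.values[np.ix_(rows, ld_col_block)] == 0).all()

    def test_case_study_table_shape_and_order(self, small_matrices):
        disease = small_matrices.diseases[3]
        table = case_study(disease, small_matrices, params=FAST, top_k=5, seed=1)
        assert len(table) == 5
        assert (table["disease"] == disease).all()
        assert (np.diff(table["score"].to_numpy()) <= 0).all()

    def test_planted_disease_recovers_cluster_lncrnas(self, small_bundle, small_matrices):
        """Held-out disease's top candidates are enriched for its cluster."""
        from rflda.synthetic import cluster_assignment

        config = small_bundle.config
        dc = cluster_assignment(config.n_disease, config.n_clusters)
        lc = cluster_assignment(config.n_lncrna, config.n_clusters)
        disease = config.diseases[0]
        cluster = dc[0]
        table = case_study(
            disease,
            small_matrices,
            params=ForestParams(n_trees=100, seed=2),
            top_k=8,
            seed=2,
        )
        lnc_cluster = {l: c for l, c in zip(config.lncrnas, lc)}
        hits = sum(lnc_cluster[l] == cluster for l in table["lncRNA"])
        base_rate = np.mean(lc == cluster)
        assert hits / len(table) > 2 * base_rate

    def test_unknown_disease(self, small_matrices):
        with pytest.raises(KeyError):
            case_study("not-a-disease", small_matrices, params=FAST)


class TestFacade:
    def test_fit_predict_summary(self, small_bundle):
        model = RFLDA(
            small_bundle.ld,
            small_bundle.md,
            small_bundle.lm,
            small_bundle.ontology,
            params=ForestParams(n_trees=30, seed=0),
        )
        results = model.fit(n_importance_runs=2, k=20)
        assert len(results.subset.kept) == 20
        text = results.summary()
        assert "features selected (k):          20" in text
        table = results.predict(top_k=3)
        assert set(table.columns) == {"disease", "lncRNA", "score"}
        assert table.groupby("disease").size().max() <= 3
        # predictions exclude known associations
        known = set(small_bundle.ld.pairs())
        assert not any(
            (l, d) in known for l, d in zip(table["lncRNA"], table["disease"])
        )

    def test_fit_with_sweep_selects_best_k(self, small_bundle):
        model = RFLDA(
            small_bundle.ld,
            small_bundle.md,
            small_bundle.lm,
            small_bundle.ontology,
            params=ForestParams(n_trees=20, seed=1),
        )
        results = model.fit(
            n_importance_runs=1, sweep_ks=[5, 15], sweep_folds=3
        )
        assert results.accuracy_curve is not None
        assert len(results.subset.kept) == results.accuracy_curve.best_k
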