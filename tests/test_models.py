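"""models: NB weights/scores, forest training, importance, persistence."""

import math

import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.naive_bayes import BernoulliNB

import chemtriage as ct
from chemtriage.errors import ModelFormatError, ValidationError
from chemtriage.models import _Tree
from chemtriage.preprocess import TokenizedDocument


def matrix_from_rows(rows, labels, terms=None):
    rows = np.asarray(rows, dtype=np.int8)
    terms = terms or [f"t{j}" for j in range(rows.shape[1])]
    vocab = ct.Vocabulary.from_terms(terms)
    return ct.DocTermMatrix(
        doc_ids=[f"d{i}" for i in range(rows.shape[0])],
        vocabulary=vocab,
        bits=sp.csr_matrix(rows),
        labels=np.asarray(labels),
    )


class TestTrainNB:
    def test_balanced_feature_weight_zero(self):
        # feature present in half the positives and half the negatives: A = B/2
        rows = [[1], [1], [0], [0], [1], [1], [0], [0]]
        labels = [1, 1, 1, 1, 0, 0, 0, 0]
        model = ct.train_nb(matrix_from_rows(rows, labels))
        assert model.weights[0] == pytest.approx(0.0)

    def test_positive_only_feature_weight(self):
        # 4 positive carriers, 0 negative, balanced 8 docs: ln((4+1)/(4*0.5+1))
        rows = [[1], [1], [1], [1], [0], [0], [0], [0]]
        labels = [1, 1, 1, 1, 0, 0, 0, 0]
        model = ct.train_nb(matrix_from_rows(rows, labels))
        assert model.weights[0] == pytest.approx(math.log(5 / 3))

    def test_toy_corpus_weights_match_hand_formula(self):
        rows = [
            [1, 0, 1],
            [1, 1, 0],
            [0, 1, 1],
            [0, 0, 1],
            [1, 0, 0],
            [0, 1, 0],
        ]
        labels = [1, 1, 1, 0, 0, 0]
        m = matrix_from_rows(rows, labels)
        model = ct.train_nb(m)
        p = 0.5
        R = np.asarray(rows)
        y = np.asarray(labels)
        for j in range(3):
            a = int(R[y == 1, j].sum())
            b = int(R[:, j].sum())
            assert model.weights[j] == pytest.approx(math.log((a + 1) / (b * p + 1)))

    def test_weight_identity_property(self, study):
        """exp(weight) * (B*p + 1) == A + 1 for every feature."""
        model = study.nb
        y = study.train.labels
        bits = study.train.bits
        b = np.asarray(bits.sum(axis=0)).ravel()
        a = np.asarray(bits[y == 1].sum(axis=0)).ravel()
        lhs = np.exp(model.weights) * (b * model.prior_positive + 1)
        np.testing.assert_allclose(lhs, a + 1, rtol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            ct.train_nb(matrix_from_rows([[1], [0]], [1, 1]))

    def test_bad_prior_rejected(self):
        with pytest.raises(ValidationError):
            ct.train_nb(matrix_from_rows([[1], [0]], [1, 0]), prior=1.5)


class TestScoreNB:
    def test_all_zero_row_scores_zero(self):
        m = matrix_from_rows([[1, 1], [0, 0], [1, 0], [0, 1]], [1, 1, 0, 0])
        model = ct.train_nb(m)
        scores = model.decision_scores(m)
        assert scores[1] == pytest.approx(0.0)

    def test_scores_are_weight_sums(self):
        m = matrix_from_rows([[1, 0, 1], [1, 1, 1], [0, 0, 0], [0, 1, 0]], [1, 1, 0, 0])
        model = ct.train_nb(m)
        scores = model.decision_scores(m)
        R = np.asarray([[1, 0, 1], [1, 1, 1], [0, 0, 0], [0, 1, 0]])
        expected = R @ model.weights
        np.testing.assert_allclose(scores, expected)

    def test_adding_positive_feature_increases_score(self):
        m = matrix_from_rows([[1, 0], [1, 0], [0, 1], [0, 1]], [1, 1, 0, 0])
        model = ct.train_nb(m)
        assert model.weights[0] > 0
        without = ct.vectorize([TokenizedDocument("q", ())], m.vocabulary)
        with_f = ct.vectorize([TokenizedDocument("q", ("t0",))], m.vocabulary)
        assert model.decision_scores(with_f)[0] > model.decision_scores(without)[0]

    def test_vocabulary_mismatch_rejected(self):
        m = matrix_from_rows([[1], [0]], [1, 0])
        model = ct.train_nb(m)
        other = ct.vectorize([TokenizedDocument("q", ("zzz",))], ct.Vocabulary.from_terms(["zzz"]))
        with pytest.raises(ValidationError):
            model.decision_scores(other)


def test_bernoulli_variant_matches_sklearn():
    """Bernoulli NB log-odds agree with sklearn's BernoulliNB (alpha=1)."""
    rng = np.random.default_rng(5)
    rows = (rng.random((60, 8)) < 0.4).astype(np.int8)
    labels = rng.integers(0, 2, 60)
    labels[:2] = [0, 1]  # both classes
    m = matrix_from_rows(rows, labels)
    model = ct.train_nb(m, variant="bernoulli")
    ours = model.decision_scores(m)
    ref = BernoulliNB(alpha=1.0).fit(rows, labels)
    log_odds = ref.predict_log_proba(rows)[:, 1] - ref.predict_log_proba(rows)[:, 0]
    np.testing.assert_allclose(ours, log_odds, rtol=1e-9, atol=1e-9)


class TestNBImportance:
    def test_identity_with_model_weights(self, study):
        table = ct.nb_importance(study.nb)
        np.testing.assert_array_equal(table.importance, study.nb.weights)

    def test_zero_weight_ties_to_negative(self):
        rows = [[1], [1], [0], [0], [1], [1], [0], [0]]
        model = ct.train_nb(matrix_from_rows(rows, [1, 1, 1, 1, 0, 0, 0, 0]))
        table = ct.nb_importance(model)
        assert table.importance[0] == pytest.approx(0.0)
        assert table.class_association[0] == "negative"

    def test_magnitude_sort_matches_brute_force(self, study):
        table = ct.nb_importance(study.nb).sorted_by_magnitude()
        mags = np.abs(table.importance)
        assert np.all(mags[:-1] >= mags[1:])


class TestTrainRF:
    def test_perfectly_separating_feature(self):
        rng = np.random.default_rng(3)
        noise = (rng.random((200, 5)) < 0.3).astype(np.int8)
        labels = np.repeat([1, 0], 100)
        rows = np.column_stack([labels.astype(np.int8), noise])
        model = ct.train_rf(matrix_from_rows(rows, labels), n_trees=30, seed=3)
        oob_pred = (model.oob_scores >= 0.5).astype(int)
        acc = np.mean(oob_pred == labels)
        assert acc >= 0.95

    def test_permuted_labels_give_chance_oob_auc(self):
        rng = np.random.default_rng(9)
        rows = (rng.random((400, 40)) < 0.2).astype(np.int8)
        labels = rng.permutation(np.repeat([1, 0], 200))
        model = ct.train_rf(matrix_from_rows(rows, labels), n_trees=100, seed=9)
        auc, _ = ct.roc_auc(model.oob_scores, labels)
        assert 0.43 <= auc <= 0.57

    def test_same_seed_identical_forest(self):
        rng = np.random.default_rng(2)
        rows = (rng.random((80, 10)) < 0.3).astype(np.int8)
        labels = np.repeat([1, 0], 40)
        m = matrix_from_rows(rows, labels)
        f1 = ct.train_rf(m, n_trees=10, seed=42)
        f2 = ct.train_rf(m, n_trees=10, seed=42)
        for t1, t2 in zip(f1.trees, f2.trees):
            np.testing.assert_array_equal(t1.feature, t2.feature)
            np.testing.assert_array_equal(t1.left, t2.left)
            np.testing.assert_allclose(t1.pos_fraction, t2.pos_fraction)
        f3 = ct.train_rf(m, n_trees=10, seed=43)
        assert any(
            not np.array_equal(a.feature, b.feature) for a, b in zip(f1.trees, f3.trees)
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            ct.train_rf(matrix_from_rows([[1], [0]], [1, 1]), n_trees=2)


class TestRFTopLevelImportance:
    def _stump_forest(self, vocab_terms, feature=0):
        stump = _Tree(
            feature=np.array([feature, -1, -1]),
            left=np.array([1, -1, -1]),
            right=np.array([2, -1, -1]),
            pos_fraction=np.array([0.5, 0.1, 0.9]),
        )
        return ct.ForestModel(
            vocabulary=ct.Vocabulary.from_terms(vocab_terms),
            trees=[stump],
            threshold=0.5,
            n_pos=1,
            n_neg=1,
            seed=0,
        )

    def test_single_stump(self):
        model = self._stump_forest(["alpha", "beta"])
        table = ct.rf_top_level_importance(model)
        assert table.importance[0] == 1 and table.importance[1] == 0
        assert table.class_association[0] == "positive"

    def test_deep_node_excluded_beyond_max_level(self):
        # chain: depths 1..4 split on features 0..3
        tree = _Tree(
            feature=np.array([0, 1, -1, 2, -1, 3, -1, -1, -1]),
            left=np.array([1, 3, -1, 5, -1, 7, -1, -1, -1]),
            right=np.array([2, 4, -1, 6, -1, 8, -1, -1, -1]),
            pos_fraction=np.full(9, 0.5),
        )
        model = ct.ForestModel(
            vocabulary=ct.Vocabulary.from_terms(["a", "b", "c", "d"]),
            trees=[tree],
            threshold=0.5,
            n_pos=1,
            n_neg=1,
            seed=0,
        )
        table = ct.rf_top_level_importance(model, max_level=3)
        assert list(table.importance) == [1, 1, 1, 0]
        assert sorted(table.per_level) == [1, 2, 3]

    def test_max_level_below_one_rejected(self):
        with pytest.raises(ValidationError):
            ct.rf_top_level_importance(self._stump_forest(["a"]), max_level=0)

    def test_designated_terms_top_ranked_on_separable_data(self, study):
        table = ct.rf_top_level_importance(study.rf).sorted_by_magnitude()
        designated = set(study.corpus.pos_terms) | set(study.corpus.neg_terms)
        assert sum(t in designated for t in table.terms[:10]) >= 8


class TestPersistence:
    def test_nb_round_trip(self, tmp_path, study):
        p = tmp_path / "nb.json"
        ct.save_model(study.nb, p)
        back = ct.load_model(p)
        np.testing.assert_array_equal(back.weights, study.nb.weights)
        assert back.threshold == study.nb.threshold
        assert back.vocabulary.terms == study.nb.vocabulary.terms
        assert back.prior_positive == study.nb.prior_positive

    def test_rf_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        rows = (rng.random((60, 8)) < 0.3).astype(np.int8)
        labels = np.repeat([1, 0], 30)
        m = matrix_from_rows(rows, labels)
        model = ct.train_rf(m, n_trees=10, seed=1)
        p = tmp_path / "rf.json.gz"
        ct.save_model(model, p)
        back = ct.load_model(p)
        assert back.n_trees == 10
        for t1, t2 in zip(model.trees, back.trees):
            np.testing.assert_array_equal(t1.feature, t2.feature)
            np.testing.assert_allclose(t1.pos_fraction, t2.pos_fraction)
        np.testing.assert_allclose(model.oob_scores, back.oob_scores)
        np.testing.assert_allclose(
            model.decision_scores(m), back.decision_scores(m)
        )

    def test_corrupted_file_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("{not json")
        with pytest.raises(ModelFormatError):
            ct.load_model(p)

    def test_version_mismatch_rejected(self, tmp_path):
        p = tmp_path / "old.json"
        p.write_text('{"format_version": 99, "model_type": "nb"}')
        with pytest.raises(ModelFormatError, match="version"):
            ct.load_model(p)
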