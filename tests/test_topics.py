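"""Topic filtering: LDA fitting, dominant topics, concentration scoring, stages."""

import numpy as np
import pytest

from vaemmine.preprocess import NON_VAEM, VAEM
from vaemmine.topics import (
    ConcentrationScore,
    DataError,
    TopicModelBundle,
    apply_filter,
    concentration_score,
    dominant_topic,
    exhaustive_concentration_score,
    fit_topic_model,
    select_best_model,
    stage2_refine,
)


def fake_bundle(doc_topic: np.ndarray) -> TopicModelBundle:
    k = doc_topic.shape[1]
    return TopicModelBundle(
        n_topics=k,
        topic_word=np.full((k, 3), 1 / 3),
        doc_topic=doc_topic,
        vocabulary=("a", "b", "c"),
        seed=0,
        hyperparameters={},
    )


def one_hot(assignments, k):
    dt = np.zeros((len(assignments), k))
    dt[np.arange(len(assignments)), assignments] = 1.0
    return dt


class TestFitTopicModel:
    def test_disjoint_subjects_recovered_with_high_purity(self, disjoint_subject_corpus):
        docs, subjects = disjoint_subject_corpus
        bundle = fit_topic_model(docs, n_topics=3, seed=0, min_df=2, max_df=0.9)
        dom = bundle.dominant_topics()
        purities = []
        for k in range(3):
            topic_of = [dom[i] for i in range(len(docs)) if subjects[i] == k]
            top = np.bincount(topic_of, minlength=3).max()
            purities.append(top / len(topic_of))
        assert min(purities) >= 0.9

    def test_single_topic_all_dominant_zero(self, disjoint_subject_corpus):
        docs, _ = disjoint_subject_corpus
        bundle = fit_topic_model(docs[:50], n_topics=1, seed=0, min_df=1, max_df=1.0)
        assert set(bundle.dominant_topics()) == {0}

    def test_same_seed_identical_doc_topic(self, disjoint_subject_corpus):
        docs, _ = disjoint_subject_corpus
        a = fit_topic_model(docs, n_topics=3, seed=5, min_df=2, max_df=0.9)
        b = fit_topic_model(docs, n_topics=3, seed=5, min_df=2, max_df=0.9)
        np.testing.assert_array_equal(a.doc_topic, b.doc_topic)

    def test_row_sums_one(self, disjoint_subject_corpus):
        docs, _ = disjoint_subject_corpus
        bundle = fit_topic_model(docs, n_topics=3, seed=0, min_df=2, max_df=0.9)
        np.testing.assert_allclose(bundle.doc_topic.sum(axis=1), 1.0, atol=1e-8)
        np.testing.assert_allclose(bundle.topic_word.sum(axis=1), 1.0, atol=1e-8)

    def test_empty_vocabulary_raises(self):
        with pytest.raises(DataError):
            fit_topic_model([["a"], ["b"]], n_topics=2, min_df=10)


class TestDominantTopic:
    def test_argmax_and_tie_rule(self):
        bundle = fake_bundle(np.array([[0.1, 0.7, 0.2], [0.5, 0.5, 0.0]]))
        assert dominant_topic(bundle, 0) == 1
        assert dominant_topic(bundle, 1) == 0  # tie goes to lowest index

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(0)
        dt = rng.dirichlet(np.ones(13), size=50)
        bundle = fake_bundle(dt)
        for i in range(50):
            best, best_t = -1.0, 0
            for t in range(13):
                if dt[i, t] > best:
                    best, best_t = dt[i, t], t
            assert dominant_topic(bundle, i) == best_t


class TestConcentrationScore:
    def test_perfect_separation(self):
        assignments = [3] * 10 + [1] * 5 + [2] * 5
        labels = [VAEM] * 10 + [NON_VAEM] * 10
        bundle = fake_bundle(one_hot(assignments, 5))
        score = concentration_score(bundle, list(enumerate(labels)))
        assert score.best_topic_set == frozenset({3})
        assert score.f1 == 1.0

    def test_hand_confusion_arithmetic(self):
        # topic 0: 8 VAEM + 2 non; 2 VAEM elsewhere -> P=R=F1=0.8
        assignments = [0] * 10 + [1] * 2 + [2] * 20
        labels = [VAEM] * 8 + [NON_VAEM] * 2 + [VAEM] * 2 + [NON_VAEM] * 20
        bundle = fake_bundle(one_hot(assignments, 3))
        score = concentration_score(bundle, list(enumerate(labels)), max_topics=1)
        assert score.best_topic_set == frozenset({0})
        assert (score.precision, score.recall) == (0.8, 0.8)
        assert score.f1 == pytest.approx(0.8)

    def test_greedy_at_least_single_topic_and_at_most_exhaustive(self):
        rng = np.random.default_rng(12)
        for trial in range(20):
            k = int(rng.integers(3, 7))
            assignments = rng.integers(0, k, size=60)
            labels = [VAEM if rng.random() < 0.3 else NON_VAEM for _ in range(60)]
            if VAEM not in labels or NON_VAEM not in labels:
                continue
            bundle = fake_bundle(one_hot(assignments, k))
            labeled = list(enumerate(labels))
            greedy = concentration_score(bundle, labeled, max_topics=3)
            single_best = max(
                concentration_score(bundle, labeled, max_topics=1).f1 for _ in [0]
            )
            exhaustive = exhaustive_concentration_score(bundle, labeled, max_topics=3)
            assert greedy.f1 >= single_best
            assert greedy.f1 <= exhaustive.f1 + 1e-12

    def test_matches_confusion_matrix_oracle(self):
        from sklearn.metrics import f1_score, precision_score, recall_score

        rng = np.random.default_rng(5)
        assignments = rng.integers(0, 6, size=200)
        labels = [VAEM if rng.random() < 0.2 else NON_VAEM for _ in range(200)]
        bundle = fake_bundle(one_hot(assignments, 6))
        score = concentration_score(bundle, list(enumerate(labels)))
        y_true = np.array([lab == VAEM for lab in labels], dtype=int)
        y_pred = np.isin(assignments, list(score.best_topic_set)).astype(int)
        assert score.precision == pytest.approx(precision_score(y_true, y_pred))
        assert score.recall == pytest.approx(recall_score(y_true, y_pred))
        assert score.f1 == pytest.approx(f1_score(y_true, y_pred))

    def test_requires_both_classes(self):
        bundle = fake_bundle(one_hot([0, 1], 2))
        with pytest.raises(DataError):
            concentration_score(bundle, [(0, VAEM), (1, VAEM)])
        with pytest.raises(DataError):
            concentration_score(bundle, [(0, NON_VAEM), (1, NON_VAEM)])


class TestSelectBestModel:
    def test_single_point_grid_returns_that_model(self, disjoint_subject_corpus):
        docs, subjects = disjoint_subject_corpus
        labels = [(i, VAEM if s == 0 else NON_VAEM) for i, s in enumerate(subjects)]
        bundle, score = select_best_model(
            docs, labels, grid=[(3, 1)], min_df=2, max_df=0.9
        )
        assert bundle.n_topics == 3 and bundle.seed == 1
        assert score.model_id == "k3_s1"

    def test_separable_k_beats_degenerate_k(self, disjoint_subject_corpus):
        docs, subjects = disjoint_subject_corpus
        labels = [(i, VAEM if s == 0 else NON_VAEM) for i, s in enumerate(subjects)]
        bundle, score = select_best_model(
            docs, labels, grid=[(1, 0), (3, 0)], min_df=2, max_df=0.9
        )
        assert bundle.n_topics == 3
        assert score.f1 > 0.9

    def test_deterministic_across_reruns(self, disjoint_subject_corpus):
        docs, subjects = disjoint_subject_corpus
        labels = [(i, VAEM if s == 0 else NON_VAEM) for i, s in enumerate(subjects)]
        r1 = select_best_model(docs, labels, grid=[(3, 0), (4, 1)], min_df=2, max_df=0.9)
        r2 = select_best_model(docs, labels, grid=[(3, 0), (4, 1)], min_df=2, max_df=0.9)
        assert r1[1] == r2[1]
        np.testing.assert_array_equal(r1[0].doc_topic, r2[0].doc_topic)


class TestApplyFilter:
    def test_partition_and_monotonicity(self):
        rng = np.random.default_rng(8)
        dt = rng.dirichlet(np.ones(5), size=80)
        bundle = fake_bundle(dt)
        ids = [f"d{i}" for i in range(80)]
        small = apply_filter(bundle, frozenset({1}), ids)
        bigger = apply_filter(bundle, frozenset({1, 3}), ids)
        assert set(small.retained) | set(small.discarded) == set(ids)
        assert set(small.retained) & set(small.discarded) == set()
        assert set(small.retained) <= set(bigger.retained)

    def test_all_topics_is_identity(self):
        dt = np.random.default_rng(1).dirichlet(np.ones(4), size=30)
        bundle = fake_bundle(dt)
        ids = [str(i) for i in range(30)]
        result = apply_filter(bundle, frozenset(range(4)), ids)
        assert set(result.retained) == set(ids) and not result.discarded

    def test_unseen_documents_inferred_against_frozen_model(self, disjoint_subject_corpus):
        docs, subjects = disjoint_subject_corpus
        bundle = fit_topic_model(docs[:180], n_topics=3, seed=0, min_df=2, max_df=0.9)
        new_docs = docs[180:]
        ids = [str(i) for i in range(len(new_docs))]
        result = apply_filter(bundle, frozenset({0, 1, 2}), ids, corpus=new_docs)
        assert set(result.retained) == set(ids)

    def test_empty_input(self):
        bundle = fake_bundle(np.zeros((0, 3)))
        result = apply_filter(bundle, frozenset({0}), [])
        assert result.retained == () and result.discarded == ()


class TestStage2Refine:
    def test_top_k_selects_highest_ratio_topics(self):
        # build a corpus whose stage-2 LDA is irrelevant: we check the ratio
        # ranking logic through a model fitted on clearly separable docs
        docs, subjects = [], []
        rng = np.random.default_rng(4)
        vocabs = [[f"v{k}w{j}" for j in range(10)] for k in range(4)]
        for i in range(200):
            k = i % 4
            docs.append([vocabs[k][int(j)] for j in rng.integers(0, 10, size=8)])
            subjects.append(k)
        # subject 0 and 2 are "VAEM-rich"
        labels = [
            (i, VAEM if subjects[i] in (0, 2) and rng.random() < 0.9 else NON_VAEM)
            for i in range(200)
        ]
        ids = [str(i) for i in range(200)]
        result, bundle, ratios = stage2_refine(
            docs, ids, labels, n_topics=4, seed=0, top_k=2, min_df=2, max_df=0.9
        )
        top2 = set(np.argsort(-ratios)[:2])
        assert result.topic_set == frozenset(int(t) for t in top2)
        assert result.stage == 2

    def test_ratio_threshold_zero_is_identity(self):
        docs = [["a", "b"], ["b", "c"], ["c", "a"]] * 10
        labels = [(0, VAEM), (1, NON_VAEM)]
        ids = [str(i) for i in range(30)]
        result, _, _ = stage2_refine(
            docs, ids, labels, n_topics=3, seed=0, mode="ratio_threshold",
            ratio_threshold=0.0, min_df=1, max_df=1.0,
        )
        assert set(result.retained) == set(ids)

    def test_empty_stage1_output_rejected(self):
        with pytest.raises(DataError):
            stage2_refine([], [], [(0, VAEM)])
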