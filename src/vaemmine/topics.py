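"""Topic-model filtering selected by label concentration.

The filtering idea: train latent Dirichlet allocation (LDA) models over the
cleaned stream, assign every document its *dominant* topic (argmax of the
document-topic distribution, ties to the lowest index), and score a model by
the positive-class F1 of the predictor "dominant topic is in a chosen topic
set" against a small labeled sample.  A model scores well exactly when the
rare label of interest is concentrated in one or a few topics.  The
best-scoring model then filters the full stream; an optional second stage
refits a model on the retained documents and keeps only the topics with the
highest ratio of positive labels, trading a little recall for much higher
purity.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.decomposition import LatentDirichletAllocation
from sklearn.feature_extraction.text import CountVectorizer

from vaemmine.preprocess import VAEM


class DataError(ValueError):
    """Raised when input data cannot support the requested operation."""


@dataclass
class TopicModelBundle:
    """A fitted topic model plus its training-set dominant-topic assignments."""

    n_topics: int
    topic_word: np.ndarray  # (K, V), rows sum to 1
    doc_topic: np.ndarray  # (N, K), rows sum to 1
    vocabulary: tuple[str, ...]
    seed: int
    hyperparameters: dict
    _lda: LatentDirichletAllocation | None = None
    _vectorizer: CountVectorizer | None = None

    def infer(self, corpus: Sequence[Sequence[str]]) -> np.ndarray:
        """Document-topic distributions for unseen documents, model frozen."""
        if self._lda is None or self._vectorizer is None:
            raise DataError("bundle was loaded without its fitted estimators")
        if len(corpus) == 0:
            return np.zeros((0, self.n_topics))
        dtm = self._vectorizer.transform([list(doc) for doc in corpus])
        return self._lda.transform(dtm)

    def dominant_topics(self, doc_topic: np.ndarray | None = None) -> np.ndarray:
        dt = self.doc_topic if doc_topic is None else doc_topic
        return np.argmax(dt, axis=1)


@dataclass(frozen=True)
class ConcentrationScore:
    """Label-concentration score of a topic model.

    ``f1`` is the positive-class F1 of "dominant topic in best_topic_set"
    against the labeled sample; the set is grown greedily while F1 strictly
    improves.
    """

    model_id: str
    best_topic_set: frozenset[int]
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class FilterResult:
    retained: tuple[str, ...]
    discarded: tuple[str, ...]
    stage: int
    topic_set: frozenset[int]


def _identity_analyzer(doc):
    return doc


def fit_topic_model(
    corpus: Sequence[Sequence[str]],
    n_topics: int,
    seed: int = 0,
    doc_topic_prior: float | None = None,
    topic_word_prior: float | None = None,
    max_iter: int = 25,
    min_df: int = 5,
    max_df: float = 0.5,
) -> TopicModelBundle:
    """Fit LDA on pre-tokenized documents.

    Symmetric Dirichlet priors default to 1/K.  Vocabulary pruning drops
    tokens in fewer than ``min_df`` documents or more than ``max_df`` of
    them.  Deterministic given ``seed`` (single-threaded batch variational
    inference).
    """
    if len(corpus) == 0:
        raise DataError("corpus is empty")
    if n_topics < 1:
        raise ValueError("n_topics must be >= 1")
    alpha = doc_topic_prior if doc_topic_prior is not None else 1.0 / n_topics
    eta = topic_word_prior if topic_word_prior is not None else 1.0 / n_topics
    vectorizer = CountVectorizer(
        analyzer=_identity_analyzer, min_df=min_df, max_df=max_df, lowercase=False
    )
    try:
        dtm = vectorizer.fit_transform([list(doc) for doc in corpus])
    except ValueError as exc:
        raise DataError(f"vocabulary empty after pruning: {exc}") from exc
    if dtm.shape[1] == 0:
        raise DataError("vocabulary empty after pruning")
    lda = LatentDirichletAllocation(
        n_components=n_topics,
        doc_topic_prior=alpha,
        topic_word_prior=eta,
        max_iter=max_iter,
        learning_method="batch",
        random_state=seed,
        n_jobs=1,
    )
    doc_topic = lda.fit_transform(dtm)
    topic_word = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    return TopicModelBundle(
        n_topics=n_topics,
        topic_word=topic_word,
        doc_topic=doc_topic,
        vocabulary=tuple(vectorizer.get_feature_names_out()),
        seed=seed,
        hyperparameters={
            "doc_topic_prior": alpha,
            "topic_word_prior": eta,
            "max_iter": max_iter,
            "min_df": min_df,
            "max_df": max_df,
        },
        _lda=lda,
        _vectorizer=vectorizer,
    )


def dominant_topic(bundle: TopicModelBundle, doc_index: int) -> int:
    """Argmax topic of one document; ties break to the lowest topic index."""
    return int(np.argmax(bundle.doc_topic[doc_index]))


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return precision, recall, f1


def _score_topic_set(
    dominant: np.ndarray, positive: np.ndarray, topic_set: frozenset[int]
) -> tuple[float, float, float]:
    in_set = np.isin(dominant, list(topic_set))
    tp = int(np.sum(in_set & positive))
    fp = int(np.sum(in_set & ~positive))
    fn = int(np.sum(~in_set & positive))
    return _prf(tp, fp, fn)


def concentration_score(
    bundle: TopicModelBundle,
    labeled: Sequence[tuple[int, str]] | Mapping[int, str],
    max_topics: int = 3,
    model_id: str = "",
) -> ConcentrationScore:
    """Greedy best-subset label-concentration F1.

    Starts with the single topic whose dominant-topic predictor has the best
    positive-class F1 on the labeled sample, then adds topics while F1
    strictly improves, up to ``max_topics`` topics.  Requires at least one
    positive and one negative label.
    """
    items = list(labeled.items()) if isinstance(labeled, Mapping) else list(labeled)
    if not items:
        raise DataError("no labeled documents supplied")
    idx = np.array([i for i, _ in items], dtype=int)
    positive = np.array([lab == VAEM for _, lab in items], dtype=bool)
    if not positive.any():
        raise DataError("labeled sample contains no positive (VAEM) documents")
    if positive.all():
        raise DataError("labeled sample contains no negative documents")
    dominant = bundle.dominant_topics()[idx]

    candidates = list(range(bundle.n_topics))
    best_set: frozenset[int] = frozenset()
    best = (0.0, 0.0, 0.0)
    # seed with the best single topic (ties to the lowest index)
    for t in candidates:
        p, r, f = _score_topic_set(dominant, positive, frozenset([t]))
        if f > best[2]:
            best, best_set = (p, r, f), frozenset([t])
    if not best_set:
        best_set = frozenset([0])
        best = _score_topic_set(dominant, positive, best_set)
    # grow while F1 strictly improves
    while len(best_set) < max_topics:
        gain = None
        for t in candidates:
            if t in best_set:
                continue
            trial = best_set | {t}
            p, r, f = _score_topic_set(dominant, positive, trial)
            if f > best[2] and (gain is None or f > gain[0][2] or (f == gain[0][2] and t < min(gain[1] - best_set))):
                gain = ((p, r, f), trial)
        if gain is None:
            break
        best, best_set = gain
    return ConcentrationScore(
        model_id=model_id,
        best_topic_set=best_set,
        precision=best[0],
        recall=best[1],
        f1=best[2],
    )


def exhaustive_concentration_score(
    bundle: TopicModelBundle,
    labeled: Sequence[tuple[int, str]] | Mapping[int, str],
    max_topics: int = 3,
) -> ConcentrationScore:
    """Brute-force best subset (all subsets up to ``max_topics``); oracle for tests."""
    items = list(labeled.items()) if isinstance(labeled, Mapping) else list(labeled)
    idx = np.array([i for i, _ in items], dtype=int)
    positive = np.array([lab == VAEM for _, lab in items], dtype=bool)
    dominant = bundle.dominant_topics()[idx]
    best_set, best = frozenset([0]), (0.0, 0.0, -1.0)
    for k in range(1, max_topics + 1):
        for combo in combinations(range(bundle.n_topics), k):
            p, r, f = _score_topic_set(dominant, positive, frozenset(combo))
            if f > best[2]:
                best, best_set = (p, r, f), frozenset(combo)
    return ConcentrationScore("exhaustive", best_set, best[0], best[1], max(best[2], 0.0))


def select_best_model(
    corpus: Sequence[Sequence[str]],
    labeled: Sequence[tuple[int, str]] | Mapping[int, str],
    grid: Iterable[tuple[int, int]] = ((8, 0), (10, 0), (13, 0), (16, 0), (20, 0),
                                       (8, 1), (10, 1), (13, 1), (16, 1), (20, 1),
                                       (8, 2), (10, 2), (13, 2), (16, 2), (20, 2)),
    max_topics: int = 3,
    **fit_kwargs,
) -> tuple[TopicModelBundle, ConcentrationScore]:
    """Fit every (n_topics, seed) grid point and keep the best-concentrating model.

    Ties break toward fewer topics in the best set, then smaller n_topics,
    then lower seed, so the selection is deterministic for a fixed grid.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    winner: tuple | None = None
    for n_topics, seed in grid:
        bundle = fit_topic_model(corpus, n_topics=n_topics, seed=seed, **fit_kwargs)
        score = concentration_score(
            bundle, labeled, max_topics=max_topics, model_id=f"k{n_topics}_s{seed}"
        )
        key = (-score.f1, len(score.best_topic_set), n_topics, seed)
        if winner is None or key < winner[0]:
            winner = (key, bundle, score)
    return winner[1], winner[2]


def apply_filter(
    bundle: TopicModelBundle,
    topic_set: frozenset[int] | ConcentrationScore,
    ids: Sequence[str],
    corpus: Sequence[Sequence[str]] | None = None,
    stage: int = 1,
) -> FilterResult:
    """Retain documents whose dominant topic falls in the selected topic set.

    With ``corpus`` given, documents are inferred against the frozen model
    (the apply-to-incoming-data path); otherwise the bundle's own training
    assignments are used and ``ids`` must align with them.
    """
    if isinstance(topic_set, ConcentrationScore):
        topic_set = topic_set.best_topic_set
    if corpus is not None:
        doc_topic = bundle.infer(corpus)
    else:
        doc_topic = bundle.doc_topic
    if len(ids) != doc_topic.shape[0]:
        raise ValueError("ids must align with documents")
    if doc_topic.shape[0] == 0:
        return FilterResult((), (), stage, frozenset(topic_set))
    dominant = np.argmax(doc_topic, axis=1)
    keep = np.isin(dominant, list(topic_set))
    ids_arr = np.asarray(ids, dtype=object)
    return FilterResult(
        retained=tuple(ids_arr[keep]),
        discarded=tuple(ids_arr[~keep]),
        stage=stage,
        topic_set=frozenset(topic_set),
    )


def stage2_refine(
    corpus: Sequence[Sequence[str]],
    ids: Sequence[str],
    labeled: Sequence[tuple[int, str]] | Mapping[int, str],
    n_topics: int = 10,
    seed: int = 0,
    mode: str = "top_k",
    top_k: int = 3,
    ratio_threshold: float = 0.3,
    **fit_kwargs,
) -> tuple[FilterResult, TopicModelBundle, np.ndarray]:
    """Second-stage refinement on stage-1 output.

    Refit a topic model on the retained documents, rank topics by the ratio
    of positive (VAEM) labels among labeled documents dominantly assigned to
    each, and keep either the ``top_k`` highest-ratio topics or all topics
    with ratio >= ``ratio_threshold``.  Purity rises at the cost of some
    recall.  Returns (filter result, stage-2 bundle, per-topic ratios).
    """
    if len(corpus) == 0:
        raise DataError("stage-1 output is empty")
    bundle = fit_topic_model(corpus, n_topics=n_topics, seed=seed, **fit_kwargs)
    items = list(labeled.items()) if isinstance(labeled, Mapping) else list(labeled)
    dominant_all = bundle.dominant_topics()
    counts = np.zeros(n_topics)
    pos = np.zeros(n_topics)
    for i, lab in items:
        t = int(dominant_all[i])
        counts[t] += 1
        pos[t] += lab == VAEM
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = np.where(counts > 0, pos / np.maximum(counts, 1), 0.0)
    if mode == "top_k":
        order = np.lexsort((np.arange(n_topics), -ratios))
        keep = frozenset(int(t) for t in order[: min(top_k, n_topics)])
    elif mode == "ratio_threshold":
        keep = frozenset(int(t) for t in range(n_topics) if ratios[t] >= ratio_threshold)
    else:
        raise ValueError(f"unknown stage-2 mode {mode!r}")
    result = apply_filter(bundle, keep, ids, stage=2)
    return result, bundle, ratios
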