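"""Binary VAEM classification over filtered posts.

Covers the classification phase of the funnel: carve a holdout test set,
balance the remaining pool by undersampling negatives, split train/validation
75:25, vectorize as bag-of-words (counts or tf-idf, n-grams up to 3), train
classical classifiers plus the NBSVM log-count-ratio linear model, combine
five of them by majority vote, and report positive-class precision/recall/F1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.feature_extraction.text import CountVectorizer, TfidfVectorizer
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV, SGDClassifier
from sklearn.naive_bayes import MultinomialNB
from sklearn.svm import LinearSVC

from vaemmine.preprocess import CleanPost, NON_VAEM, VAEM

ENSEMBLE_MEMBERS = ("nbsvm", "logreg_cv", "sgd", "linear_svc", "random_forest")


@dataclass(frozen=True)
class VectorizerConfig:
    """Bag-of-words settings explored by the grid search."""

    weighting: str = "tfidf"  # "counts" or "tfidf"
    ngram_range: tuple[int, int] = (1, 2)
    remove_stopwords: bool = False
    remove_numbers: bool = True
    lowercase: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.ngram_range
        if not (1 <= lo <= hi <= 3):
            raise ValueError("ngram_range must satisfy 1 <= lo <= hi <= 3")
        if self.weighting not in ("counts", "tfidf"):
            raise ValueError("weighting must be 'counts' or 'tfidf'")

    def sort_key(self) -> tuple:
        return (
            self.weighting,
            self.ngram_range,
            self.remove_stopwords,
            self.remove_numbers,
            self.lowercase,
        )


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test posts; test is carved before balancing."""

    train: list[CleanPost]
    validation: list[CleanPost]
    test: list[CleanPost]
    balance: str = "balanced"
    name: str = ""


@dataclass(frozen=True)
class EvalReport:
    """Positive-class precision/recall/F1 with the underlying confusion counts."""

    classifier_id: str
    test_set: str
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp > 0 else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn > 0 else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r > 0 else 0.0

    def rounded(self) -> dict:
        """Display form: 3 decimals, half away from zero."""
        from vaemmine.accounting import round_half_away

        return {
            "classifier": self.classifier_id,
            "test_set": self.test_set,
            "precision": round_half_away(self.precision, 3),
            "recall": round_half_away(self.recall, 3),
            "f1": round_half_away(self.f1, 3),
        }


def report_from_counts(tp: int, fp: int, fn: int, tn: int, classifier_id: str = "", test_set: str = "") -> EvalReport:
    return EvalReport(classifier_id, test_set, tp, fp, fn, tn)


# --- data sets -------------------------------------------------------------


def make_balanced_set(
    pool: Sequence[CleanPost],
    seed: int = 0,
    test_fraction: float = 0.15,
    validation_fraction: float = 0.25,
    name: str = "",
) -> DatasetSplit:
    """Holdout-then-balance dataset construction.

    A label-stratified holdout test set (``test_fraction`` of the pool,
    imbalanced, reflecting how filtering delivers data) is carved out first.
    The rest is balanced by randomly undersampling negatives to the positive
    count, every positive retained, then split 75:25 into train/validation,
    stratified.  Seed-reproducible.
    """
    pos = [p for p in pool if p.label == VAEM]
    neg = [p for p in pool if p.label == NON_VAEM]
    if not pos or not neg:
        raise ValueError("pool must contain both VAEM and NON_VAEM posts")
    rng = np.random.default_rng(seed)

    def carve(group: list[CleanPost], frac: float) -> tuple[list[CleanPost], list[CleanPost]]:
        order = rng.permutation(len(group))
        n_held = int(round(len(group) * frac))
        held = [group[int(i)] for i in order[:n_held]]
        rest = [group[int(i)] for i in order[n_held:]]
        return held, rest

    test_pos, pos_rest = carve(pos, test_fraction)
    test_neg, neg_rest = carve(neg, test_fraction)
    n_match = min(len(pos_rest), len(neg_rest))
    neg_sampled = [neg_rest[int(i)] for i in rng.permutation(len(neg_rest))[:n_match]]
    pos_rest = pos_rest[:n_match] if len(pos_rest) > n_match else pos_rest

    def split_tv(group: list[CleanPost]) -> tuple[list[CleanPost], list[CleanPost]]:
        order = rng.permutation(len(group))
        n_val = int(round(len(group) * validation_fraction))
        val = [group[int(i)] for i in order[:n_val]]
        tr = [group[int(i)] for i in order[n_val:]]
        return tr, val

    tr_pos, val_pos = split_tv(pos_rest)
    tr_neg, val_neg = split_tv(neg_sampled)
    return DatasetSplit(
        train=tr_pos + tr_neg,
        validation=val_pos + val_neg,
        test=test_pos + test_neg,
        balance="balanced",
        name=name,
    )


# --- vectorization ---------------------------------------------------------

_TOKEN_PATTERN = r"(?u)\b\w[\w_]*\b"
_NO_DIGIT_TOKEN_PATTERN = r"(?u)\b[^\W\d][\w_]*\b"


def build_vectorizer(cfg: VectorizerConfig):
    kwargs = dict(
        ngram_range=cfg.ngram_range,
        stop_words="english" if cfg.remove_stopwords else None,
        lowercase=cfg.lowercase,
        token_pattern=_NO_DIGIT_TOKEN_PATTERN if cfg.remove_numbers else _TOKEN_PATTERN,
    )
    if cfg.weighting == "tfidf":
        return TfidfVectorizer(**kwargs)
    return CountVectorizer(**kwargs)


def vectorize(corpus: Sequence[str], cfg: VectorizerConfig):
    """Fit a document-term matrix; returns (sparse matrix, fitted vectorizer)."""
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    vec = build_vectorizer(cfg)
    try:
        X = vec.fit_transform(corpus)
    except ValueError as exc:
        raise ValueError(f"empty vocabulary under this config: {exc}") from exc
    return X, vec


# --- NBSVM -----------------------------------------------------------------


class NBSVM(BaseEstimator, ClassifierMixin):
    """Linear classifier over naive-Bayes log-count-ratio scaled features.

    The per-feature ratio is ``r = log(((p + alpha)/||p + alpha||_1) /
    ((q + alpha)/||q + alpha||_1))`` with ``p``/``q`` the summed feature
    counts of positive/negative documents.  A logistic model is fitted on
    ``X * r`` and its weights interpolated toward their mean magnitude:
    ``w' = beta * w + (1 - beta) * mean(|w|)``, which regularizes rare
    features toward the naive-Bayes solution.
    """

    def __init__(self, alpha: float = 1.0, beta: float = 0.25, C: float = 1.0, seed: int = 0):
        self.alpha = alpha
        self.beta = beta
        self.C = C
        self.seed = seed

    @staticmethod
    def log_count_ratio(X, y, alpha: float = 1.0) -> np.ndarray:
        X = sp.csr_matrix(X)
        y = np.asarray(y)
        p = np.asarray(X[y == 1].sum(axis=0)).ravel() + alpha
        q = np.asarray(X[y == 0].sum(axis=0)).ravel() + alpha
        return np.log((p / p.sum()) / (q / q.sum()))

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("NBSVM is a binary classifier")
        y01 = (y == self.classes_[1]).astype(int)
        self.r_ = self.log_count_ratio(X, y01, self.alpha)
        Xs = sp.csr_matrix(X).multiply(self.r_).tocsr()
        base = LogisticRegression(C=self.C, max_iter=1000, random_state=self.seed)
        base.fit(Xs, y01)
        w = base.coef_.ravel()
        w_bar = np.abs(w).mean()
        self.coef_ = self.beta * w + (1 - self.beta) * w_bar
        self.intercept_ = base.intercept_[0] * self.beta
        return self

    def decision_function(self, X):
        Xs = sp.csr_matrix(X).multiply(self.r_).tocsr()
        return Xs @ self.coef_ + self.intercept_

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


# --- classifier registry ---------------------------------------------------


def make_classifier(name: str, seed: int = 0):
    """Instantiate a classifier by registry name; unknown names are config errors."""
    registry = {
        "logreg_cv": lambda: LogisticRegressionCV(cv=5, max_iter=2000, random_state=seed),
        "sgd": lambda: SGDClassifier(random_state=seed),
        "linear_svc": lambda: LinearSVC(random_state=seed),
        "random_forest": lambda: RandomForestClassifier(
            n_estimators=200, random_state=seed, n_jobs=1
        ),
        "extra_trees": lambda: ExtraTreesClassifier(
            n_estimators=200, random_state=seed, n_jobs=1
        ),
        "multinomial_nb": lambda: MultinomialNB(),
        "nbsvm": lambda: NBSVM(seed=seed),
        "xgboost": _xgb_factory(seed),
    }
    if name not in registry:
        raise ValueError(f"unknown classifier spec {name!r}; known: {sorted(registry)}")
    return registry[name]()


def _xgb_factory(seed: int):
    def make():
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=200,
            max_depth=6,
            learning_rate=0.2,
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
        )

    return make


@dataclass
class TrainedModel:
    """A fitted vectorizer + classifier pair with its provenance."""

    spec: str
    vectorizer_config: VectorizerConfig
    vectorizer: object
    classifier: object
    seed: int

    def predict_labels(self, texts: Sequence[str]) -> np.ndarray:
        X = self.vectorizer.transform(texts)
        pred = self.classifier.predict(X)
        return np.asarray(pred)


def _texts(posts: Sequence[CleanPost]) -> list[str]:
    return [p.norm_text for p in posts]


def _y(posts: Sequence[CleanPost]) -> np.ndarray:
    return np.array([1 if p.label == VAEM else 0 for p in posts])


def train(
    spec: str,
    split: DatasetSplit,
    vec_cfg: VectorizerConfig | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit one registry classifier on the split's training texts."""
    if not split.train or not split.validation:
        raise ValueError("split must have non-empty train and validation sets")
    vec_cfg = vec_cfg or VectorizerConfig()
    X, vec = vectorize(_texts(split.train), vec_cfg)
    clf = make_classifier(spec, seed=seed)
    clf.fit(X, _y(split.train))
    return TrainedModel(spec, vec_cfg, vec, clf, seed)


def ensemble_vote(predictions: Sequence[Sequence[int]]) -> np.ndarray:
    """Per-document majority over an odd number of binary label vectors."""
    votes = np.asarray(predictions, dtype=int)
    if votes.ndim != 2:
        raise ValueError("predictions must be a 2-D (voters x documents) array")
    if votes.shape[0] % 2 == 0:
        raise ValueError("voter count must be odd (majority tie undefined)")
    return (votes.sum(axis=0) * 2 > votes.shape[0]).astype(int)


def evaluate(
    model: TrainedModel | Sequence[int],
    test: Sequence[CleanPost],
    positive_label: str = VAEM,
    test_set_name: str = "test",
) -> EvalReport:
    """Positive-class EvalReport for a model (or raw prediction vector) on a test set."""
    y_true = np.array([1 if p.label == positive_label else 0 for p in test])
    if isinstance(model, TrainedModel):
        y_pred = np.asarray(model.predict_labels(_texts(test)), dtype=int)
        cid = model.spec
    else:
        y_pred = np.asarray(model, dtype=int)
        cid = "predictions"
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    return EvalReport(cid, test_set_name, tp, fp, fn, tn)


def grid_search(
    vec_grid: Sequence[VectorizerConfig],
    clf_specs: Sequence[str],
    split: DatasetSplit,
    seed: int = 0,
):
    """Train every (vectorizer, classifier) combination; rank by validation F1.

    Ties break toward fewer features, then lexical config order.  Returns a
    pandas DataFrame log sorted best-first.
    """
    import pandas as pd

    if not vec_grid or not clf_specs:
        raise ValueError("grids must be non-empty")
    rows = []
    for vc in vec_grid:
        for spec in sorted(clf_specs):
            model = train(spec, split, vec_cfg=vc, seed=seed)
            rep = evaluate(model, split.validation, test_set_name="validation")
            rows.append(
                {
                    "classifier": spec,
                    "vectorizer": vc,
                    "n_features": len(model.vectorizer.vocabulary_),
                    "precision": rep.precision,
                    "recall": rep.recall,
                    "f1": rep.f1,
                }
            )
    frame = pd.DataFrame(rows)
    frame["_cfg_order"] = [
        (r["classifier"],) + r["vectorizer"].sort_key() for r in rows
    ]
    frame = frame.sort_values(
        by=["f1", "n_features", "_cfg_order"], ascending=[False, True, True]
    ).drop(columns="_cfg_order")
    return frame.reset_index(drop=True)


# --- embeddings ------------------------------------------------------------


@dataclass
class EmbeddingTable:
    """Dense word vectors; unknown tokens map to the zero vector."""

    vocabulary: dict[str, int]
    vectors: np.ndarray
    dimension: int
    window: int
    seed: int

    def __getitem__(self, token: str) -> np.ndarray:
        j = self.vocabulary.get(token)
        if j is None:
            return np.zeros(self.dimension)
        return self.vectors[j]

    def cosine(self, a: str, b: str) -> float:
        va, vb = self[a], self[b]
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0 or nb == 0:
            return 0.0
        return float(va @ vb / (na * nb))


def train_embeddings(
    corpus: Sequence[Sequence[str]],
    dimension: int = 100,
    window: int = 5,
    seed: int = 0,
    min_count: int = 5,
) -> EmbeddingTable:
    """Count-based skip-gram-style embeddings via PPMI + truncated SVD.

    Symmetric-window co-occurrence counts are reweighted to positive
    pointwise mutual information and factorized with a seeded truncated SVD;
    this is the classical count-based counterpart of skip-gram training and
    is exactly reproducible.  Requires at least 100 documents.
    """
    if len(corpus) < 100:
        raise ValueError("need at least 100 documents to train embeddings")
    from collections import Counter

    freq = Counter(tok for doc in corpus for tok in doc)
    vocab = {t: j for j, t in enumerate(sorted(t for t, c in freq.items() if c >= min_count))}
    if not vocab:
        raise ValueError("no tokens pass min_count")
    rows, cols, vals = [], [], []
    cooc: Counter = Counter()
    for doc in corpus:
        idx = [vocab[t] for t in doc if t in vocab]
        for i, wi in enumerate(idx):
            for j in range(max(0, i - window), min(len(idx), i + window + 1)):
                if j != i:
                    cooc[(wi, idx[j])] += 1
    total = sum(cooc.values())
    word_marg = Counter()
    for (a, b), c in cooc.items():
        word_marg[a] += c
    for (a, b), c in cooc.items():
        pmi = np.log((c * total) / (word_marg[a] * word_marg[b]))
        if pmi > 0:
            rows.append(a)
            cols.append(b)
            vals.append(pmi)
    V = len(vocab)
    M = sp.csr_matrix((vals, (rows, cols)), shape=(V, V))
    k = min(dimension, V - 1)
    if k < 1:
        vectors = np.zeros((V, dimension))
    else:
        from scipy.sparse.linalg import svds

        rng = np.random.default_rng(seed)
        v0 = rng.standard_normal(min(M.shape))
        u, s, _ = svds(M.asfptype(), k=k, v0=v0)
        order = np.argsort(-s)
        emb = u[:, order] * np.sqrt(s[order])
        vectors = np.zeros((V, dimension))
        vectors[:, :k] = emb
    return EmbeddingTable(vocab, vectors, dimension, window, seed)
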