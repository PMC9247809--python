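"""Text normalization, deduplication, and phrase building for short posts.

The cleaning pipeline mirrors the standard preparation of keyword-collected
tweet streams: strip URLs and @-mentions, lowercase, keep hashtag words but
drop the ``#``, remove punctuation and digits, collapse whitespace, drop
duplicates (by id or exact text) and posts shorter than ``min_words`` words,
then merge high-scoring collocations (``flu shot`` -> ``flu_shot``) so topic
models see multiword phrases as single tokens.
"""

from __future__ import annotations

import csv
import json
import math
import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

VAEM = "VAEM"
NON_VAEM = "NON_VAEM"
UNLABELED = "UNLABELED"
LABELS = (VAEM, NON_VAEM, UNLABELED)

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_MENTION_RE = re.compile(r"@\w+")
_NON_ALPHA_RE = re.compile(r"[^a-z0-9\s]+")
_DIGIT_RE = re.compile(r"[0-9]+")
_WS_RE = re.compile(r"\s+")


@dataclass(frozen=True)
class Post:
    """One raw social-media record."""

    id: str
    text: str
    created_at: str | None = None
    label: str = UNLABELED

    def __post_init__(self) -> None:
        if not isinstance(self.text, str):
            raise TypeError(f"post text must be str, got {type(self.text).__name__}")
        if not self.id:
            raise ValueError("post id must be non-empty")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class CleanPost:
    """A normalized post: lowercase text, word tokens, phrase-merged tokens."""

    id: str
    norm_text: str
    tokens: tuple[str, ...]
    ngram_tokens: tuple[str, ...]
    label: str = UNLABELED


@dataclass(frozen=True)
class CleaningConfig:
    min_words: int = 5
    keep_hashtag_words: bool = True
    phrase_max_n: int = 3
    phrase_min_count: int = 5
    phrase_threshold: float = 10.0


def normalize_text(text: str, cfg: CleaningConfig | None = None) -> str:
    """Normalize one post's text to a lowercase ``[a-z ]*`` string.

    Removal order: URLs, @-mentions, lowercasing, ``#`` stripping (the tag
    word itself is kept by default, since collection keywords like "flushot"
    often occur only as hashtags), punctuation/symbols, digits, whitespace
    collapse.  Unicode is NFKC-folded first; emoji and non-Latin symbols are
    dropped with the punctuation class.  Idempotent.
    """
    if not isinstance(text, str):
        raise TypeError(f"expected str, got {type(text).__name__}")
    cfg = cfg or CleaningConfig()
    out = unicodedata.normalize("NFKC", text)
    out = _URL_RE.sub(" ", out)
    out = _MENTION_RE.sub(" ", out)
    out = out.lower()
    if not cfg.keep_hashtag_words:
        out = re.sub(r"#\w+", " ", out)
    # a remaining '#' falls to the punctuation class below; the tag word survives
    out = _NON_ALPHA_RE.sub(" ", out)
    out = _DIGIT_RE.sub(" ", out)
    out = _WS_RE.sub(" ", out).strip()
    return out


def deduplicate(posts: Sequence[Post]) -> list[Post]:
    """Drop posts whose id or exact text was already seen; first wins, order kept."""
    seen_ids: set[str] = set()
    seen_texts: set[str] = set()
    out: list[Post] = []
    for post in posts:
        dup = post.id in seen_ids or post.text in seen_texts
        # every prior post's id/text counts as seen, kept or not
        seen_ids.add(post.id)
        seen_texts.add(post.text)
        if not dup:
            out.append(post)
    return out


def filter_short(posts: Sequence[CleanPost], min_words: int = 5) -> list[CleanPost]:
    """Keep posts with at least ``min_words`` tokens (strict "<min_words removed")."""
    if min_words < 1:
        raise ValueError("min_words must be >= 1")
    return [p for p in posts if len(p.tokens) >= min_words]


def _phrase_score(
    pair_count: int, a_count: int, b_count: int, vocab_size: int, min_count: int
) -> float:
    # Collocation score: (count(ab) - min_count) * |V| / (count(a) * count(b)).
    return (pair_count - min_count) * vocab_size / (a_count * b_count)


def build_phrases(
    corpus: Sequence[Sequence[str]],
    max_n: int = 3,
    min_count: int = 5,
    threshold: float = 10.0,
) -> list[list[str]]:
    """Merge frequent contiguous collocations into single ``a_b`` tokens.

    One merge pass joins bigrams whose collocation score exceeds
    ``threshold``; passes are iterated ``max_n - 1`` times so phrases up to
    ``max_n`` words can form.  Deterministic for fixed input;
    ``threshold=inf`` is the identity transform.
    """
    if not corpus:
        raise ValueError("corpus must be non-empty")
    docs = [list(doc) for doc in corpus]
    for _ in range(max(0, max_n - 1)):
        if math.isinf(threshold):
            break
        unigram = Counter(tok for doc in docs for tok in doc)
        bigram = Counter(
            (doc[i], doc[i + 1]) for doc in docs for i in range(len(doc) - 1)
        )
        vocab_size = len(unigram)
        merges = {
            pair
            for pair, c in bigram.items()
            if c >= min_count
            and _phrase_score(c, unigram[pair[0]], unigram[pair[1]], vocab_size, min_count)
            > threshold
        }
        if not merges:
            break
        new_docs = []
        for doc in docs:
            merged: list[str] = []
            i = 0
            while i < len(doc):
                if i + 1 < len(doc) and (doc[i], doc[i + 1]) in merges:
                    merged.append(doc[i] + "_" + doc[i + 1])
                    i += 2
                else:
                    merged.append(doc[i])
                    i += 1
            new_docs.append(merged)
        docs = new_docs
    return docs


def clean_corpus(posts: Sequence[Post], cfg: CleaningConfig | None = None) -> list[CleanPost]:
    """Full cleaning pass: dedupe -> normalize -> length filter -> phrases."""
    cfg = cfg or CleaningConfig()
    unique = deduplicate(posts)
    cleaned = []
    for post in unique:
        norm = normalize_text(post.text, cfg)
        tokens = tuple(norm.split())
        if tokens:
            cleaned.append(
                CleanPost(id=post.id, norm_text=norm, tokens=tokens, ngram_tokens=tokens, label=post.label)
            )
    cleaned = filter_short(cleaned, cfg.min_words)
    if not cleaned:
        return []
    phrased = build_phrases(
        [list(p.tokens) for p in cleaned],
        max_n=cfg.phrase_max_n,
        min_count=cfg.phrase_min_count,
        threshold=cfg.phrase_threshold,
    )
    return [replace(p, ngram_tokens=tuple(doc)) for p, doc in zip(cleaned, phrased)]


# ---------------------------------------------------------------------------
# I/O: JSONL (one object per line) and CSV with id/text/created_at/label columns.


def read_posts(path: str | Path) -> list[Post]:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _read_posts_csv(path)
    return _read_posts_jsonl(path)


def _coerce_post(rec: dict) -> Post:
    label = rec.get("label") or UNLABELED
    created = rec.get("created_at") or None
    return Post(id=str(rec["id"]), text=str(rec["text"]), created_at=created, label=label)


def _read_posts_jsonl(path: Path) -> list[Post]:
    posts = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                posts.append(_coerce_post(json.loads(line)))
    return posts


def _read_posts_csv(path: Path) -> list[Post]:
    with open(path, encoding="utf-8", newline="") as fh:
        return [_coerce_post(row) for row in csv.DictReader(fh)]


def write_clean_posts(posts: Iterable[CleanPost], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in posts:
            fh.write(
                json.dumps(
                    {
                        "id": p.id,
                        "norm_text": p.norm_text,
                        "tokens": list(p.tokens),
                        "ngram_tokens": list(p.ngram_tokens),
                        "label": p.label,
                    }
                )
                + "\n"
            )


def read_clean_posts(path: str | Path) -> list[CleanPost]:
    posts = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            posts.append(
                CleanPost(
                    id=str(rec["id"]),
                    norm_text=rec["norm_text"],
                    tokens=tuple(rec["tokens"]),
                    ngram_tokens=tuple(rec["ngram_tokens"]),
                    label=rec.get("label", UNLABELED),
                )
            )
    return posts
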