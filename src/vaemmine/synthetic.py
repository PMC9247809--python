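"""Synthetic vaccine-conversation corpus with ground-truth subjects and labels.

Real keyword-collected vaccine streams are dominated by a dozen-plus broad
subjects (policy fights, outbreak news, research, conspiracy talk, school
paperwork, pet vaccination, ...) of which exactly one is "personal health
mention"-like.  Vaccine adverse event mentions (VAEMs) sit almost entirely
inside that one subject, at a global prevalence near 1.45%, surrounded by
hard negatives that reuse the same symptom and vaccine vocabulary in
non-personal frames (news reports, sarcasm).  The generator reproduces that
structure with template-filled posts over subject-specific vocabularies, so
the topic filter has a real signal to find and classifiers must read frames,
not just keywords.

Surface noise (hashtags, @-mentions, URLs, punctuation, stray digits,
capitalization) is sprinkled on top so the cleaning stage has real work to
do; the underlying content tokens always number at least 5, so posts survive
the short-post filter by construction and cleaning losses come from
duplicates only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from vaemmine.preprocess import NON_VAEM, UNLABELED, VAEM, Post

# --- vocabulary banks ------------------------------------------------------

VACCINE_WORDS = (
    "vaccine vaccines vaccination vax flu shot flushot jab dose booster "
    "immunization clinic pharmacy nurse doctor"
).split()

SYMPTOM_WORDS = (
    "sore ache fever feverish headache dizzy nausea tired exhausted swollen "
    "rash chills pain numb throbbing itchy weak"
).split()

BODY_WORDS = "arm shoulder head stomach leg muscle neck back skin".split()

PERSONAL_WORDS = (
    "i my me got feel feeling today yesterday after now really still cant "
    "literally honestly so ugh omg whole day night woke barely hurts hurt bad"
).split()

FRAME_WORDS = (
    "news study report researchers officials health department says new free "
    "offering available week read more apparently they people everyone "
    "supposedly claims warns"
).split()

FUNCTION_WORDS = (
    "the a to of and in for is on it this that with are be at was have about "
    "from not but you your they we what when"
).split()

# Twelve non-personal subjects; each list is (mostly) disjoint from the others
# and from the symptom/body/personal banks, so subjects are topically separable.
SUBJECT_THEMES: tuple[tuple[str, ...], ...] = tuple(
    tuple(s.split())
    for s in (
        "mandate mandates law bill government state require required exemption "
        "workplace policy debate rights freedom choice enforce legislation "
        "senate vote public",
        "measles outbreak cases confirmed county region spread epidemic "
        "warning alert infected quarantine emergency response reported rise "
        "surge area community plea",
        "trial data results published journal scientists efficacy immune "
        "response antibodies phase participants findings evidence peer review "
        "lab university research personalized",
        "truth hidden agenda pharma corrupt media lies wake sheep control "
        "toxins chemicals natural detox cover conspiracy secret profit scam hoax",
        "school kids children parents enrollment forms records grade "
        "kindergarten teacher district office paperwork deadline year checkup "
        "pediatrician appointment form registration",
        "travel trip abroad passport airport country destination yellow "
        "typhoid malaria tablets visa vacation flight packing advice "
        "checklist itinerary overseas border",
        "dog cat puppy kitten vet veterinarian rabies annual pet paws tail "
        "groomer kennel adoption shelter microchip treats litter leash collar",
        "pfizer moderna merck stock shares market quarter revenue earnings "
        "fda approval pipeline biotech investors company billion supply "
        "contract deal analysts",
        "season hospital admissions rate percent peak strain circulating "
        "surveillance severity activity levels statistics elderly deaths "
        "weekly numbers charts trends milder",
        "celebrity star actress singer interview posted instagram video fans "
        "viral tweet said backlash comments followers podcast show host "
        "famous trending",
        "mom dad baby toddler parenting forum group advice schedule delayed "
        "spacing worried anxious decision discussion opinions judgment mommy "
        "playgroup naps",
        "polio smallpox history eradicated decades century disease deadly "
        "saved millions lives generation grandparents remember iron lung "
        "historical medicine science textbook",
    )
)

# Templates: "{v}"=vaccine word, "{s}"=symptom, "{b}"=body part.
VAEM_TEMPLATES = (
    "aw my poor {b} is {s} from my {v}",
    "got my {v} yesterday and now i feel {s} and {s}",
    "my {b} hurts so bad after the {v} i can barely move it",
    "woke up {s} and {s} the day after my {v} ugh",
    "that {v} made my whole {b} {s} for days",
    "i got the {v} this morning and my {b} is already {s}",
    "feeling {s} and my {b} is {s} after my {v} today",
    "cant lift my {b} after my {v} and i feel {s} too",
)

BENIGN_WORDS = (
    "fine easy painless quick great glad done finally proud relieved smooth "
    "no problems covered free early appointment booked ready"
).split()

# Hard negatives inside the personal-health subject: mostly personal in frame
# (so they share the VAEM topic through both filtering stages) but benign or
# non-personal in substance -- only a classifier reading context separates them.
HARD_NEGATIVE_TEMPLATES = (
    "got my {v} today and it was totally fine didnt even notice",
    "taking the kids to the clinic for their {v} tomorrow morning",
    "so glad i finally got my {v} this year feeling great about it",
    "my {v} appointment was quick and painless the nurse was lovely",
    "just booked my {v} for next week everyone should get one",
    "apparently the {v} gives you a {s} {b} lol sure it does",
    "new report says {v} linked to {s} {b} read more at",
    "they claim the {v} made everyone {s} which is obviously nonsense",
    "imagine blaming your {s} {b} on a {v} people are wild",
    "health department says a {s} {b} after a {v} is normal and passes",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic stream."""

    n_posts: int = 100_000
    n_subjects: int = 13
    vaem_subject_index: int = 0
    global_vaem_prevalence: float = 0.0145
    within_subject_vaem_ratio: float = 0.5
    vocab_size_per_subject: int = 20
    hard_negative_rate: float = 0.10
    stray_vaem_rate: float = 0.01
    duplicate_rate: float = 0.01
    mean_length: float = 18.0
    min_length: int = 5
    max_length: int = 50
    noise_rate: float = 0.6
    exact_counts: bool = False
    seed: int = 7

    def validate(self) -> None:
        if not 0 <= self.global_vaem_prevalence < 1:
            raise ValueError("global_vaem_prevalence must be in [0, 1)")
        if not 0 < self.within_subject_vaem_ratio <= 1:
            raise ValueError("within_subject_vaem_ratio must be in (0, 1]")
        if not 0 <= self.vaem_subject_index < self.n_subjects:
            raise ValueError("vaem_subject_index out of range")
        if self.n_subjects - 1 > len(SUBJECT_THEMES):
            raise ValueError(
                f"at most {len(SUBJECT_THEMES) + 1} subjects supported"
            )
        if self.exact_counts and 0 < self.global_vaem_prevalence and (
            round(self.n_posts * self.global_vaem_prevalence) < 1
        ):
            raise ValueError("exact_counts with prevalence*n_posts < 1 is infeasible")


@dataclass(frozen=True)
class SyntheticPost(Post):
    """A generated post carrying its ground-truth generating subject."""

    subject_id: int = -1


def _zipf_weights(n: int) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


def _draw_theme_words(rng: np.random.Generator, theme: Sequence[str], k: int) -> list[str]:
    vocab = list(theme)
    idx = rng.choice(len(vocab), size=k, p=_zipf_weights(len(vocab)))
    return [vocab[i] for i in idx]


def _pad_words(rng: np.random.Generator, pools: Sequence[Sequence[str]], probs: Sequence[float], k: int) -> list[str]:
    out = []
    pool_idx = rng.choice(len(pools), size=k, p=np.asarray(probs) / np.sum(probs))
    for j in pool_idx:
        pool = pools[j]
        out.append(pool[int(rng.integers(len(pool)))])
    return out


def _fill_template(rng: np.random.Generator, template: str) -> list[str]:
    words = []
    for tok in template.split():
        if tok == "{v}":
            words.append(VACCINE_WORDS[int(rng.integers(len(VACCINE_WORDS)))])
        elif tok == "{s}":
            words.append(SYMPTOM_WORDS[int(rng.integers(len(SYMPTOM_WORDS)))])
        elif tok == "{b}":
            words.append(BODY_WORDS[int(rng.integers(len(BODY_WORDS)))])
        else:
            words.append(tok)
    return words


def _target_length(rng: np.random.Generator, cfg: GeneratorConfig) -> int:
    return int(np.clip(rng.poisson(cfg.mean_length), cfg.min_length, cfg.max_length))


def _vaem_tokens(rng: np.random.Generator, cfg: GeneratorConfig) -> list[str]:
    words = _fill_template(rng, VAEM_TEMPLATES[int(rng.integers(len(VAEM_TEMPLATES)))])
    extra = _target_length(rng, cfg) - len(words)
    if extra > 0:
        # padding is deliberately close to the hard-negative padding so the
        # two classes share a topic; the signal is in the template words
        words += _pad_words(
            rng,
            (PERSONAL_WORDS, SYMPTOM_WORDS, BODY_WORDS, VACCINE_WORDS, FUNCTION_WORDS),
            (0.45, 0.10, 0.05, 0.20, 0.20),
            extra,
        )
    return words


def _hard_negative_tokens(rng: np.random.Generator, cfg: GeneratorConfig) -> list[str]:
    words = _fill_template(
        rng, HARD_NEGATIVE_TEMPLATES[int(rng.integers(len(HARD_NEGATIVE_TEMPLATES)))]
    )
    extra = _target_length(rng, cfg) - len(words)
    if extra > 0:
        words += _pad_words(
            rng,
            (PERSONAL_WORDS, BENIGN_WORDS, VACCINE_WORDS, FUNCTION_WORDS, FRAME_WORDS),
            (0.45, 0.10, 0.20, 0.20, 0.05),
            extra,
        )
    return words


def _subject_tokens(rng: np.random.Generator, cfg: GeneratorConfig, theme: Sequence[str]) -> list[str]:
    length = _target_length(rng, cfg)
    n_theme = max(1, int(round(length * 0.55)))
    words = _draw_theme_words(rng, theme[: cfg.vocab_size_per_subject], n_theme)
    rest = length - n_theme
    if rest > 0:
        words += _pad_words(
            rng, (FUNCTION_WORDS, VACCINE_WORDS, FRAME_WORDS), (0.5, 0.3, 0.2), rest
        )
    if rng.random() < cfg.hard_negative_rate:
        # non-personal symptom mention inside an off-topic subject
        words += [
            "reports",
            "of",
            SYMPTOM_WORDS[int(rng.integers(len(SYMPTOM_WORDS)))],
            "after",
            VACCINE_WORDS[int(rng.integers(len(VACCINE_WORDS)))],
        ]
    order = rng.permutation(len(words))
    return [words[i] for i in order]


def _stray_vaem_tokens(rng: np.random.Generator, cfg: GeneratorConfig, theme: Sequence[str]) -> list[str]:
    # A VAEM buried in another subject's wording: most tokens off-topic, with a
    # short personal clause.  These are the tail the topic filter loses.
    base = _subject_tokens(rng, cfg, theme)
    clause = [
        "my",
        BODY_WORDS[int(rng.integers(len(BODY_WORDS)))],
        "is",
        SYMPTOM_WORDS[int(rng.integers(len(SYMPTOM_WORDS)))],
        "from",
        "my",
        VACCINE_WORDS[int(rng.integers(len(VACCINE_WORDS)))],
    ]
    cut = max(1, len(base) - len(clause))
    return base[:cut] + clause


def _add_surface_noise(rng: np.random.Generator, words: list[str], cfg: GeneratorConfig) -> str:
    text = " ".join(words)
    if rng.random() < cfg.noise_rate:
        kind = rng.integers(4)
        if kind == 0:
            text += f" #{VACCINE_WORDS[int(rng.integers(len(VACCINE_WORDS)))]}"
        elif kind == 1:
            text = f"@user{int(rng.integers(10_000))} " + text
        elif kind == 2:
            text += f" http://t.co/{int(rng.integers(100_000)):x}"
        else:
            text += f" {int(rng.integers(2, 99))}"
    if rng.random() < 0.5:
        text = text[0].upper() + text[1:]
    if rng.random() < 0.4:
        text += rng.choice([".", "!", "!!", "..."])
    return text


def generate(cfg: GeneratorConfig) -> list[SyntheticPost]:
    """Draw a labeled corpus under ``cfg``; bit-identical for a fixed seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_posts

    if cfg.exact_counts:
        n_vaem = int(round(n * cfg.global_vaem_prevalence))
    else:
        n_vaem = int(rng.binomial(n, cfg.global_vaem_prevalence))
    is_vaem = np.zeros(n, dtype=bool)
    if n_vaem:
        is_vaem[rng.choice(n, size=n_vaem, replace=False)] = True

    # subject weights for non-VAEM posts: the VAEM subject gets exactly the
    # hard-negative mass implied by within_subject_vaem_ratio; the rest is
    # spread unevenly (Zipf-flavored) over the other subjects.
    expected_vaem_in_subject = n_vaem * (1.0 - cfg.stray_vaem_rate)
    n_hard_neg = int(
        round(expected_vaem_in_subject * (1.0 - cfg.within_subject_vaem_ratio) / cfg.within_subject_vaem_ratio)
    )
    other_subjects = [k for k in range(cfg.n_subjects) if k != cfg.vaem_subject_index]
    other_w = 0.5 + _zipf_weights(len(other_subjects))  # mildly uneven
    other_w = other_w / other_w.sum()

    posts: list[SyntheticPost] = []
    neg_subject_draws = rng.choice(len(other_subjects), size=n, p=other_w)
    hard_neg_left = n_hard_neg
    day_minutes = 0
    for i in range(n):
        if is_vaem[i]:
            label = VAEM
            if rng.random() < cfg.stray_vaem_rate:
                subject = other_subjects[int(neg_subject_draws[i])]
                words = _stray_vaem_tokens(rng, cfg, _theme_for(subject, cfg))
            else:
                subject = cfg.vaem_subject_index
                words = _vaem_tokens(rng, cfg)
        else:
            label = NON_VAEM
            if hard_neg_left > 0 and rng.random() < hard_neg_left / max(1, n - i):
                subject = cfg.vaem_subject_index
                words = _hard_negative_tokens(rng, cfg)
                hard_neg_left -= 1
            else:
                subject = other_subjects[int(neg_subject_draws[i])]
                words = _subject_tokens(rng, cfg, _theme_for(subject, cfg))
        text = _add_surface_noise(rng, words, cfg)
        day_minutes += int(rng.integers(1, 10))
        posts.append(
            SyntheticPost(
                id=f"t{i:07d}",
                text=text,
                created_at=f"2018-02-07T00:00:00Z+{day_minutes}min",
                label=label,
                subject_id=subject,
            )
        )

    # duplicates: copies of earlier posts under fresh ids (caught by text
    # dedupe); a copy is always inserted after its source so first-wins
    # deduplication retains the original
    if cfg.duplicate_rate > 0 and n > 1:
        out: list[SyntheticPost] = []
        j = 0
        for i, post in enumerate(posts):
            out.append(post)
            if i > 0 and rng.random() < cfg.duplicate_rate:
                src = posts[int(rng.integers(0, i + 1))]
                out.append(
                    SyntheticPost(
                        id=f"d{j:07d}",
                        text=src.text,
                        created_at=src.created_at,
                        label=src.label,
                        subject_id=src.subject_id,
                    )
                )
                j += 1
        posts = out
    return posts


def _theme_for(subject: int, cfg: GeneratorConfig) -> tuple[str, ...]:
    """Theme bank for a non-VAEM subject index (skipping the VAEM subject)."""
    slot = subject if subject < cfg.vaem_subject_index else subject - 1
    return SUBJECT_THEMES[slot]


def split_fixture(
    corpus: Sequence[Post],
    fractions: tuple[float, float, float] = (0.75, 0.25, 0.0),
    seed: int = 0,
) -> tuple[list[Post], list[Post], list[Post]]:
    """Label-stratified, seed-reproducible (train, valid, test) partition.

    Within each label class, posts are shuffled and allotted to the three
    splits by largest-remainder apportionment, so each split's class ratio is
    within one post of the global ratio.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    splits: tuple[list[Post], list[Post], list[Post]] = ([], [], [])
    by_label: dict[str, list[Post]] = {}
    for post in corpus:
        by_label.setdefault(post.label, []).append(post)
    n_total = len(corpus)
    targets = [f * n_total for f in fractions]
    allocated = [0, 0, 0]
    for label in sorted(by_label):
        group = by_label[label]
        order = rng.permutation(len(group))
        n = len(group)
        quotas = [f * n for f in fractions]
        counts = [int(q) for q in quotas]
        rem = n - sum(counts)
        # remainders by largest fractional part; ties to the split furthest
        # below its global target, so overall sizes come out exact
        by_frac = sorted(
            range(3),
            key=lambda j: (
                -(quotas[j] - counts[j]),
                -(targets[j] - allocated[j] - counts[j]),
                j,
            ),
        )
        for j in by_frac[:rem]:
            counts[j] += 1
        start = 0
        for j in range(3):
            for idx in order[start : start + counts[j]]:
                splits[j].append(group[int(idx)])
            allocated[j] += counts[j]
            start += counts[j]
    return splits


def subject_unigram_distributions(
    posts: Sequence[SyntheticPost], vocab: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Per-subject unigram distributions over a shared vocabulary (for diagnostics)."""
    from collections import Counter

    from vaemmine.preprocess import CleaningConfig, normalize_text

    counts: dict[int, Counter] = {}
    for p in posts:
        toks = normalize_text(p.text, CleaningConfig()).split()
        counts.setdefault(p.subject_id, Counter()).update(toks)
    if vocab is None:
        vocab = sorted({t for c in counts.values() for t in c})
    subjects = sorted(counts)
    mat = np.zeros((len(subjects), len(vocab)))
    index = {t: j for j, t in enumerate(vocab)}
    for i, s in enumerate(subjects):
        for t, c in counts[s].items():
            if t in index:
                mat[i, index[t]] = c
    mat += 1e-12
    mat /= mat.sum(axis=1, keepdims=True)
    return mat, list(vocab)


def write_corpus(posts: Sequence[SyntheticPost], path: str | Path, sidecar: str | Path | None = None) -> None:
    """Write the JSONL dialect preprocess reads, plus a ground-truth sidecar CSV."""
    import json

    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for p in posts:
            fh.write(
                json.dumps(
                    {"id": p.id, "text": p.text, "created_at": p.created_at, "label": UNLABELED}
                )
                + "\n"
            )
    if sidecar is not None:
        with open(sidecar, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "label", "subject_id"])
            for p in posts:
                w.writerow([p.id, p.label, p.subject_id])
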