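# Methods

## The problem

Keyword-collected vaccine conversation streams (e.g., tweets matching
"vaccine", "flu shot", ...) contain a small fraction — around 1.45% — of
*vaccine adverse event mentions* (VAEMs): first-person reports of feeling
unwell after a vaccination.  The rest is policy argument, outbreak news,
research chatter, conspiracy talk, school paperwork, pet vaccination, and —
hardest of all — posts that use the same symptom and vaccine vocabulary in
non-personal or benign-personal frames ("free flu shots this week", "got my
shot, didn't even hurt").  Labeling the raw stream is infeasible and a
classifier trained on it faces extreme class imbalance, so the package
implements a two-phase funnel: unsupervised topic filtering that concentrates
the rare class into a manageable sub-stream, then supervised classification
over that sub-stream.

## Phase 1: topic filtering selected by label concentration

Latent Dirichlet allocation (LDA) is fitted to the cleaned, phrase-merged
stream for each point of a grid over the topic count `K` and the training
seed.  Every document receives a *dominant topic*: the argmax of its
topic distribution, with ties broken toward the lowest topic index.  A
candidate model is scored on a small labeled sample (default 2,000 posts) by
the positive-class F1 of the hard predictor

    predict VAEM  iff  dominant_topic(d) ∈ T

where the topic set `T` is grown greedily: start from the best single topic
by F1, add topics only while F1 strictly improves, stop at `max_topics`
(default 3).  A model scores well exactly when VAEMs concentrate in one or a
few topics.  Greedy subset growth is used because exhaustive subset search is
exponential in `K`; a brute-force oracle over all subsets for `K ≤ 6` is kept
in the test suite and the greedy result is verified to lie between the best
single topic and the exhaustive optimum.  Ties between grid points break
toward fewer topics in `T`, then smaller `K`, then lower seed, making
selection deterministic.

The selected model filters the stream by dominant-topic membership.  A
second stage refits a smaller LDA on the retained documents, ranks its
topics by the share of VAEM among labeled documents dominantly assigned to
each, and keeps either the top-k topics (default 3, the funnel default) or
all topics above a ratio threshold (default 0.3).  Stage 2 trades a little
recall for a large purity gain.

Numerical/structural choices:

* **Inference.** scikit-learn's batch variational LDA, single-threaded,
  `random_state` fixed; symmetric Dirichlet priors default to `1/K`.
  Variational batch inference converges in tens of passes on corpora of this
  kind; the standalone default is 25 passes and the pipeline uses 15.
* **Vocabulary pruning.** Tokens in fewer than 5 documents or more than 50%
  of documents are dropped; an empty pruned vocabulary is a data error.
* **Model selection cost.** The pipeline fits the selection grid
  (`K ∈ {8, 10, 13, 16, 20}` × 2 seeds) on a 12k-document subsample, then
  refits the winning `(K, seed)` on the full corpus and re-derives the topic
  set on the full-corpus model.  These problem sizes are the package's
  defaults for desk-scale runs; all of them are configuration fields.
* **Stage-2 granularity.** The pipeline refits 5 topics at stage 2.  With
  many more topics than sub-themes in the retained stream, LDA fragments the
  rare class into tiny pure topics and top-k-by-ratio then collapses recall;
  5 topics keeps the mass topics mixed, reproducing the intended
  purity-up/recall-slightly-down behavior.  `stage2_refine` itself defaults
  to 10 topics for standalone use.
* **Unseen documents** are inferred against the frozen vectorizer + LDA
  (no refit), which is the apply-to-incoming-data path.

## Phase 2: classification

The labeled stage-2 output is split into an untouched, imbalanced holdout
test set (15%), then balanced by randomly undersampling negatives to the
positive count, then split 75:25 into train/validation, stratified.  Texts
are vectorized as bag-of-words (counts or tf-idf, n-grams up to 3, optional
stop-word and digit removal) and fed to a registry of classical models:
logistic regression with cross-validated regularization, a stochastic
gradient linear model, a linear SVM, random forest, extremely randomized
trees, multinomial naive Bayes, gradient-boosted trees (XGBoost), and NBSVM.

NBSVM uses the smoothed naive-Bayes log-count ratio

    r = log( ((p + α)/‖p + α‖₁) / ((q + α)/‖q + α‖₁) ),   α = 1,

with `p`, `q` the summed feature counts of positive/negative training
documents; a logistic model is fitted on `X·r` and its weights interpolated
toward their mean magnitude, `w' = βw + (1 − β)·mean(|w|)` with β = 0.25,
which pulls rare features toward the naive-Bayes solution.

Five of the linear/ensemble members (NBSVM, logistic CV, SGD, linear SVC,
random forest) are combined by per-document majority vote over predicted
labels; even voter counts are rejected because the tie is undefined.
Evaluation always reports the positive (VAEM) class: precision, recall, F1,
and the underlying confusion counts; display rounding is 3 decimals,
half away from zero.  Word embeddings for downstream sequence models are
provided as a count-based skip-gram analogue: positive pointwise mutual
information over a symmetric context window factorized by a seeded truncated
SVD, exactly reproducible, with out-of-vocabulary tokens mapped to the zero
vector.  Neural sequence classifiers themselves are out of the core; the
registry accepts any external estimator with fit/predict.

## Funnel and effectiveness accounting

`build_funnel` turns an initial count and ordered signed deltas into running
totals with percent-of-initial at 2 decimals, rounded half away from zero —
this rounding reproduces every percentage printed in the motivating study's
tables.  `estimate_effectiveness` extrapolates a classifier's recall `r` and
precision `p` over the `V` positives and `N` negatives that survived
filtering:

    TP ≈ round(r·V),  predicted positives ≈ round(TP/p),  FP = predicted − TP,

and converts the topic filter's capture rate `c` into an estimate of the
original positive count, `V₀ ≈ round(V/c)`.  Published estimates stated as
counts are accepted directly (a rate printed at 3 decimals does not invert
to the underlying count); the end-to-end capture percentage takes the
externally estimated pipeline-surviving positive count as an argument.

## The synthetic stream

Because the original tweets are not redistributable, the generator emulates
the stream's statistical structure rather than its surface text:

* 13 latent subjects, one of which is the personal-health-mention subject;
  12 themed vocabularies (policy, outbreak news, research, conspiracy,
  school, travel, pets, pharma business, season statistics, celebrity,
  parenting, disease history) plus shared vaccine keywords and function
  words.
* VAEM prevalence 1.45% globally, drawn Binomial(n, 0.0145) (an exact-count
  mode exists for deterministic funnel tests); VAEMs are template-filled
  first-person + body-part + symptom + vaccine sentences.
* Within the personal-health subject, half the posts are hard negatives
  (the 0.5 within-subject ratio is a configuration default): benign
  first-person vaccine mentions and sarcastic/news frames that reuse symptom
  words.  Their padding vocabulary deliberately overlaps the VAEM padding so
  the two classes share a topic and only classification separates them.
* 1% of VAEMs are *strays* embedded in other subjects' wording — the tail
  that topic filtering loses.
* Post length is Poisson(18) truncated to [5, 50] content tokens, so every
  post survives the shorter-than-5-words filter; cleaning losses come from
  duplicated posts (1% rate, copies always inserted after their source).
* Surface noise (hashtags, @-mentions, URLs, digits, punctuation,
  capitalization) exercises the normalizer without affecting content tokens.

What passing tests on this stream do **not** show: robustness to spelling
variation, code-switching, sarcasm beyond the included templates, topic
drift over time, or prevalence shifts — template-generated text is far
cleaner than real social-media language, which is why the synthetic
end-to-end F1 (≈1.0) exceeds what the same models achieve on real streams
(≈0.8–0.9).  The synthetic run validates the *machinery* (filtering keeps
the rare class, purity rises, classifiers resolve the remainder,
everything is seed-reproducible), not absolute real-world scores.

## Degenerate inputs and edge rules

Empty normalized text is allowed and filtered by the length rule; dedupe
counts every prior post's id and text as seen, kept or not, first
occurrence wins; `K = 1` topic models assign everything to topic 0;
concentration scoring requires at least one positive and one negative
label; a single-class classification pool, an even ensemble, zero
denominators, and negative funnel totals are all rejected with explicit
errors; an all-negative predictor scores F1 = 0, never NaN.

## Known limitations

* Topic-model quality is the binding constraint: if LDA merges the
  personal-health subject into a broad topic, stage-1 retention grows and
  purity falls; the concentration score is exactly the diagnostic for this.
* Majority voting uses hard labels, not probabilities.
* Effectiveness estimates are point estimates; no uncertainty is propagated.
* The generator's subjects are static; no temporal structure is emulated.
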