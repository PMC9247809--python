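"""End-to-end two-phase mining workflow as a model/results pair.

:class:`VaemMine` is constructed from raw posts (plus labels for at least a
small sample) and a :class:`PipelineConfig`; :meth:`VaemMine.fit` runs

    clean -> select & fit stage-1 topic model -> filter -> stage-2 refine ->
    build balanced data sets -> train classifiers -> evaluate -> account

and returns a :class:`VaemMineResults` carrying the funnel ledger, the
selected topic model and its concentration score, per-classifier evaluation
reports, ground-truth diagnostics when full labels are available, and a
``summary()`` table.  ``results.apply(new_posts)`` runs the frozen models
over incoming data (the apply path of the workflow).

Every random choice derives from ``config.seed``, so two fits with the same
configuration are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from vaemmine.accounting import FunnelLedger, build_funnel, ratio_pct
from vaemmine.classify import (
    ENSEMBLE_MEMBERS,
    DatasetSplit,
    EvalReport,
    TrainedModel,
    VectorizerConfig,
    ensemble_vote,
    evaluate,
    make_balanced_set,
    train,
)
from vaemmine.preprocess import (
    NON_VAEM,
    UNLABELED,
    VAEM,
    CleaningConfig,
    CleanPost,
    Post,
    clean_corpus,
)
from vaemmine.topics import (
    ConcentrationScore,
    DataError,
    TopicModelBundle,
    apply_filter,
    concentration_score,
    fit_topic_model,
    select_best_model,
    stage2_refine,
)


@dataclass(frozen=True)
class PipelineConfig:
    """Seeds, grids, and stage settings for a full run."""

    cleaning: CleaningConfig = CleaningConfig()
    k_grid: tuple[int, ...] = (8, 10, 13, 16, 20)
    n_model_seeds: int = 2
    selection_subsample: int = 12_000
    lda_max_iter: int = 15
    max_topics: int = 3
    labeled_sample_size: int = 2_000
    stage2_labeled_budget: int = 4_000
    stage2_n_topics: int = 5
    stage2_mode: str = "top_k"
    stage2_top_k: int = 3
    stage2_ratio_threshold: float = 0.3
    classifiers: tuple[str, ...] = (
        "nbsvm",
        "logreg_cv",
        "sgd",
        "linear_svc",
        "random_forest",
        "extra_trees",
        "multinomial_nb",
        "xgboost",
    )
    vectorizer: VectorizerConfig = VectorizerConfig()
    test_fraction: float = 0.15
    min_df: int = 5
    max_df: float = 0.5
    seed: int = 7

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class VaemMine:
    """Two-phase rare-mention mining model over a stream of posts.

    Parameters
    ----------
    posts : raw posts (id, text, optional label).
    labels : optional id -> label mapping overriding the posts' own labels;
        at least a small labeled sample (both classes) is required to score
        topic models and train classifiers.
    config : pipeline settings; defaults mirror a desk-scale study.
    """

    def __init__(
        self,
        posts: Sequence[Post],
        labels: Mapping[str, str] | None = None,
        config: PipelineConfig | None = None,
    ):
        self.posts = list(posts)
        self.config = config or PipelineConfig()
        self._labels = dict(labels) if labels is not None else None

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, config: PipelineConfig | None = None) -> "VaemMine":
        """Build from a DataFrame with columns id, text and optionally created_at, label."""
        posts = [
            Post(
                id=str(row["id"]),
                text=str(row["text"]),
                created_at=str(row["created_at"]) if "created_at" in frame.columns and pd.notna(row.get("created_at")) else None,
                label=row["label"] if "label" in frame.columns and row.get("label") in (VAEM, NON_VAEM) else UNLABELED,
            )
            for _, row in frame.iterrows()
        ]
        return cls(posts, config=config)

    # -- helpers -----------------------------------------------------------

    def _label_of(self, post_id: str, fallback: str) -> str:
        if self._labels is not None:
            return self._labels.get(post_id, fallback)
        return fallback

    def fit(self) -> "VaemMineResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        n_initial = len(self.posts)
        if n_initial == 0:
            raise DataError("no posts supplied")

        # 1. cleaning -----------------------------------------------------
        cleaned = clean_corpus(self.posts, cfg.cleaning)
        if self._labels is not None:
            cleaned = [
                CleanPost(p.id, p.norm_text, p.tokens, p.ngram_tokens, self._label_of(p.id, p.label))
                for p in cleaned
            ]
        n_clean = len(cleaned)
        if n_clean == 0:
            raise DataError("no posts survived cleaning")
        tokens = [list(p.ngram_tokens) for p in cleaned]
        labels = [p.label for p in cleaned]
        labeled_idx_all = [i for i, lab in enumerate(labels) if lab != UNLABELED]
        if not labeled_idx_all:
            raise DataError("no labeled posts available for topic scoring")

        # 2. model selection on a subsample -------------------------------
        n_sub = min(cfg.selection_subsample, n_clean)
        sub_idx = np.sort(rng.choice(n_clean, size=n_sub, replace=False))
        sub_tokens = [tokens[int(i)] for i in sub_idx]
        sub_labeled = [
            (j, labels[int(i)])
            for j, i in enumerate(sub_idx)
            if labels[int(i)] != UNLABELED
        ]
        if len(sub_labeled) > cfg.labeled_sample_size:
            pick = rng.choice(len(sub_labeled), size=cfg.labeled_sample_size, replace=False)
            sub_labeled = [sub_labeled[int(k)] for k in np.sort(pick)]
        model_seeds = [int((cfg.seed + 7919 * (j + 1)) % (2**31)) for j in range(cfg.n_model_seeds)]
        grid = [(k, s) for k in cfg.k_grid for s in model_seeds]
        _, sel_score = select_best_model(
            sub_tokens,
            sub_labeled,
            grid=grid,
            max_topics=cfg.max_topics,
            max_iter=cfg.lda_max_iter,
            min_df=cfg.min_df,
            max_df=cfg.max_df,
        )
        best_k = int(sel_score.model_id.split("_")[0][1:])
        best_seed = int(sel_score.model_id.split("_s")[1])

        # 3. stage-1 model on the full corpus -----------------------------
        stage1_bundle = fit_topic_model(
            tokens,
            n_topics=best_k,
            seed=best_seed,
            max_iter=cfg.lda_max_iter,
            min_df=cfg.min_df,
            max_df=cfg.max_df,
        )
        full_labeled = labeled_idx_all
        if len(full_labeled) > cfg.labeled_sample_size:
            pick = rng.choice(len(full_labeled), size=cfg.labeled_sample_size, replace=False)
            full_labeled = [full_labeled[int(k)] for k in np.sort(pick)]
        scoring_sample = [(i, labels[i]) for i in full_labeled]
        stage1_score = concentration_score(
            stage1_bundle, scoring_sample, max_topics=cfg.max_topics, model_id=sel_score.model_id
        )
        ids = [p.id for p in cleaned]
        stage1_result = apply_filter(stage1_bundle, stage1_score, ids, stage=1)
        retained_set = set(stage1_result.retained)
        retained_idx = [i for i, p in enumerate(cleaned) if p.id in retained_set]

        # 4. stage-2 refinement -------------------------------------------
        corpus2 = [tokens[i] for i in retained_idx]
        ids2 = [ids[i] for i in retained_idx]
        labels2 = [labels[i] for i in retained_idx]
        labeled2 = [(j, lab) for j, lab in enumerate(labels2) if lab != UNLABELED]
        if len(labeled2) > cfg.stage2_labeled_budget:
            pick = rng.choice(len(labeled2), size=cfg.stage2_labeled_budget, replace=False)
            labeled2 = [labeled2[int(k)] for k in np.sort(pick)]
        stage2_result, stage2_bundle, stage2_ratios = stage2_refine(
            corpus2,
            ids2,
            labeled2,
            n_topics=min(cfg.stage2_n_topics, max(2, len(corpus2) // 10)),
            seed=model_seeds[0],
            mode=cfg.stage2_mode,
            top_k=cfg.stage2_top_k,
            ratio_threshold=cfg.stage2_ratio_threshold,
            max_iter=cfg.lda_max_iter,
            min_df=min(cfg.min_df, max(1, len(corpus2) // 200)),
            max_df=cfg.max_df,
        )
        retained2_set = set(stage2_result.retained)

        # 5. classification datasets and training -------------------------
        pool = [
            cleaned[i]
            for i in retained_idx
            if cleaned[i].id in retained2_set and cleaned[i].label != UNLABELED
        ]
        split_seed = int((cfg.seed + 104729) % (2**31))
        split = make_balanced_set(
            pool, seed=split_seed, test_fraction=cfg.test_fraction, name="synthetic-holdout"
        )
        models: dict[str, TrainedModel] = {}
        reports: list[EvalReport] = []
        clf_seed = int((cfg.seed + 15485863) % (2**31))
        for spec in cfg.classifiers:
            model = train(spec, split, vec_cfg=cfg.vectorizer, seed=clf_seed)
            models[spec] = model
            reports.append(evaluate(model, split.test, test_set_name=split.name))
        member_specs = [s for s in ENSEMBLE_MEMBERS if s in models]
        ensemble_report = None
        if len(member_specs) % 2 == 1 and len(member_specs) >= 3:
            votes = [
                models[s].predict_labels([p.norm_text for p in split.test])
                for s in member_specs
            ]
            voted = ensemble_vote(votes)
            ensemble_report = evaluate(list(voted), split.test, test_set_name=split.name)
            ensemble_report = EvalReport(
                "ensemble", split.name, ensemble_report.tp, ensemble_report.fp,
                ensemble_report.fn, ensemble_report.tn,
            )
            reports.append(ensemble_report)

        # 6. funnel and ground-truth diagnostics --------------------------
        funnel = build_funnel(
            n_initial,
            [
                ("after cleaning", n_clean - n_initial),
                ("after stage 1", len(retained_idx) - n_clean),
                ("after stage 2", len(retained2_set) - len(retained_idx)),
            ],
        )
        truth = None
        if all(lab != UNLABELED for lab in labels):
            vaem_clean = sum(lab == VAEM for lab in labels)
            vaem_s1 = sum(labels[i] == VAEM for i in retained_idx)
            vaem_s2 = sum(1 for p in pool if p.label == VAEM)
            truth = {
                "vaem_after_cleaning": vaem_clean,
                "prevalence_after_cleaning_pct": ratio_pct(vaem_clean, n_clean),
                "stage1_retention_pct": ratio_pct(len(retained_idx), n_clean),
                "stage1_vaem_recall_pct": ratio_pct(vaem_s1, vaem_clean) if vaem_clean else None,
                "stage1_vaem_purity_pct": ratio_pct(vaem_s1, len(retained_idx)) if retained_idx else None,
                "stage2_retention_pct": ratio_pct(len(retained2_set), n_clean),
                "stage2_vaem_recall_pct": ratio_pct(vaem_s2, vaem_clean) if vaem_clean else None,
                "stage2_vaem_purity_pct": ratio_pct(vaem_s2, len(retained2_set)) if retained2_set else None,
            }

        return VaemMineResults(
            model=self,
            config=cfg,
            funnel=funnel,
            selection_score=sel_score,
            stage1_bundle=stage1_bundle,
            stage1_score=stage1_score,
            stage1_result=stage1_result,
            stage2_bundle=stage2_bundle,
            stage2_result=stage2_result,
            stage2_ratios=stage2_ratios,
            split=split,
            trained_models=models,
            reports=reports,
            ground_truth=truth,
            model_seeds=model_seeds,
        )


@dataclass
class VaemMineResults:
    """Fitted artifacts, reports, and diagnostics of one pipeline run."""

    model: VaemMine
    config: PipelineConfig
    funnel: FunnelLedger
    selection_score: ConcentrationScore
    stage1_bundle: TopicModelBundle
    stage1_score: ConcentrationScore
    stage1_result: object
    stage2_bundle: TopicModelBundle
    stage2_result: object
    stage2_ratios: np.ndarray
    split: DatasetSplit
    trained_models: dict[str, TrainedModel]
    reports: list[EvalReport]
    ground_truth: dict | None
    model_seeds: list[int]

    @property
    def report_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame([r.rounded() | {"tp": r.tp, "fp": r.fp, "fn": r.fn, "tn": r.tn} for r in self.reports])
        return frame.sort_values("f1", ascending=False).reset_index(drop=True)

    @property
    def best_classifier(self) -> EvalReport:
        return max(self.reports, key=lambda r: (r.f1, r.classifier_id))

    def provenance(self) -> dict:
        import vaemmine

        return {
            "package_version": vaemmine.__version__,
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "model_seeds": self.model_seeds,
            "stage1_model": self.stage1_score.model_id,
            "stage1_topics": sorted(self.stage1_score.best_topic_set),
            "stage2_topics": sorted(self.stage2_result.topic_set),
        }

    def summary(self) -> str:
        lines = ["VAEM-Mine pipeline run", "=" * 60]
        lines.append(self.funnel.render())
        lines.append("")
        lines.append(
            f"stage-1 model {self.stage1_score.model_id}: topics "
            f"{sorted(self.stage1_score.best_topic_set)}, concentration F1 "
            f"{self.stage1_score.f1:.3f} (P {self.stage1_score.precision:.3f}, "
            f"R {self.stage1_score.recall:.3f})"
        )
        lines.append(
            f"stage-2 retained topics {sorted(self.stage2_result.topic_set)} "
            f"({self.config.stage2_mode})"
        )
        if self.ground_truth:
            gt = self.ground_truth
            lines.append("")
            lines.append("ground truth (synthetic labels):")
            for key, val in gt.items():
                lines.append(f"  {key}: {val}")
        lines.append("")
        lines.append("positive-class test-set scores:")
        frame = self.report_frame
        lines.append(frame.to_string(index=False))
        return "\n".join(lines)

    def apply(self, new_posts: Sequence[Post]) -> dict:
        """Run the frozen models over incoming posts (apply mode).

        Returns per-stage retained ids and the best classifier's predicted
        VAEM ids.  Zero posts in, zero retained out, no error.
        """
        cleaned = clean_corpus(list(new_posts), self.config.cleaning)
        if not cleaned:
            return {"cleaned": [], "stage1": [], "stage2": [], "predicted_vaem": []}
        tokens = [list(p.ngram_tokens) for p in cleaned]
        ids = [p.id for p in cleaned]
        s1 = apply_filter(self.stage1_bundle, self.stage1_score, ids, corpus=tokens, stage=1)
        keep1 = set(s1.retained)
        idx1 = [i for i, pid in enumerate(ids) if pid in keep1]
        tokens1 = [tokens[i] for i in idx1]
        ids1 = [ids[i] for i in idx1]
        if ids1:
            s2 = apply_filter(
                self.stage2_bundle, self.stage2_result.topic_set, ids1, corpus=tokens1, stage=2
            )
        else:
            s2 = None
        keep2 = set(s2.retained) if s2 else set()
        final_posts = [cleaned[i] for i in idx1 if cleaned[i].id in keep2]
        best_spec = max(
            (r for r in self.reports if r.classifier_id in self.trained_models),
            key=lambda r: r.f1,
            default=None,
        )
        predicted = []
        if final_posts and best_spec is not None:
            model = self.trained_models[best_spec.classifier_id]
            preds = model.predict_labels([p.norm_text for p in final_posts])
            predicted = [p.id for p, yhat in zip(final_posts, preds) if int(yhat) == 1]
        return {
            "cleaned": [p.id for p in cleaned],
            "stage1": list(s1.retained),
            "stage2": sorted(keep2),
            "predicted_vaem": predicted,
        }
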