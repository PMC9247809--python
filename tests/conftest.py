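"""Shared fixtures: all test data is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

import vaemmine as vm
from vaemmine.pipeline import PipelineConfig, VaemMine


@pytest.fixture(scope="session")
def small_corpus():
    """A 4k-post synthetic stream with ground-truth labels and subjects."""
    return vm.generate(vm.GeneratorConfig(n_posts=4000, seed=11))


@pytest.fixture(scope="session")
def small_cleaned(small_corpus):
    return vm.clean_corpus(small_corpus)


@pytest.fixture(scope="session")
def disjoint_subject_corpus():
    """Three subjects with fully disjoint vocabularies; trivial for LDA."""
    rng = np.random.default_rng(3)
    vocabs = [[f"s{k}w{j}" for j in range(20)] for k in range(3)]
    docs, subjects = [], []
    for i in range(240):
        k = i % 3
        docs.append([vocabs[k][int(j)] for j in rng.integers(0, 20, size=12)])
        subjects.append(k)
    return docs, subjects


def scaled_pipeline_config(seed: int = 7) -> PipelineConfig:
    """Desk-scale pipeline settings used by the pipeline tests."""
    return PipelineConfig(
        seed=seed,
        k_grid=(8, 13),
        n_model_seeds=1,
        selection_subsample=4000,
        labeled_sample_size=1500,
        classifiers=("nbsvm", "logreg_cv", "sgd", "linear_svc", "random_forest"),
    )


@pytest.fixture(scope="session")
def small_pipeline_results():
    """One fitted pipeline on a 6k-post stream (reused across tests)."""
    posts = vm.generate(vm.GeneratorConfig(n_posts=6000, seed=7))
    return VaemMine(posts, config=scaled_pipeline_config()).fit()
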