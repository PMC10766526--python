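"""Shared fixtures: one mid-sized synthetic cohort with planted category
structure, its trained and rotated embedding, and small helpers."""

from __future__ import annotations

import numpy as np
import pytest

import nspace as ns


@pytest.fixture(scope="session")
def default_cfg() -> ns.SimulationConfig:
    return ns.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def bundle(default_cfg):
    """(vocab, corpus, genotypes, truth) for the default 5,000-patient cohort."""
    vocab, truth0 = ns.make_vocabulary(default_cfg)
    geno = ns.simulate_genotypes(default_cfg)
    corpus, truth = ns.simulate_cohort(default_cfg, (vocab, truth0), geno)
    return vocab, corpus, geno, truth


@pytest.fixture(scope="session")
def vocab(bundle):
    return bundle[0]


@pytest.fixture(scope="session")
def corpus(bundle):
    return bundle[1]


@pytest.fixture(scope="session")
def genotypes(bundle):
    return bundle[2]


@pytest.fixture(scope="session")
def truth(bundle):
    return bundle[3]


@pytest.fixture(scope="session")
def embedding(corpus, vocab):
    """Rotated 20-dimensional embedding trained on the default cohort."""
    return ns.pca_rotate(ns.train_embeddings(corpus, vocab, seed=1))


@pytest.fixture(scope="session")
def traits(corpus, embedding):
    return ns.corpus_traits(corpus, embedding)


@pytest.fixture()
def toy_embedding():
    """Deterministic 6-disease, 3-dimension matrix for query unit tests."""
    coords = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, 1.0, 0.0],
            [0.0, 0.0, 1.0],
            [1.0, 1.0, 0.0],
            [-1.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],
        ]
    )
    tokens = ("a", "b", "c", "ab", "neg_a", "a_dup")
    return ns.EmbeddingMatrix(tokens=tokens, coords=coords)
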