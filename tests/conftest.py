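"""Shared fixtures: a seeded synthetic world (corpus + dictionaries +
embedding clusters + extractor) and small hand-built sentences."""

from types import SimpleNamespace

import pytest

from drugner.corpus import sentence_from_text
from drugner.features import SentenceFeatureExtractor, fit_embedding_clusters
from drugner.synthetic import (
    GeneratorConfig,
    generate_corpus,
    generate_dictionaries,
    generate_embeddings,
)

SEED = 11


@pytest.fixture(scope="session")
def world():
    """An 80-sentence synthetic corpus with its resources, built once."""
    cfg = GeneratorConfig(seed=SEED, n_sentences=80)
    corpus, lexicons = generate_corpus(cfg)
    dictionaries = generate_dictionaries(corpus, coverage=0.8, seed=SEED)
    words, vectors = generate_embeddings(corpus, dim=12, seed=SEED)
    cluster_model = fit_embedding_clusters(words, vectors, k=6, seed=SEED)
    extractor = SentenceFeatureExtractor(
        dictionaries=dictionaries, cluster_model=cluster_model
    )
    return SimpleNamespace(
        config=cfg,
        corpus=corpus,
        lexicons=lexicons,
        dictionaries=dictionaries,
        embedding_words=words,
        embedding_vectors=vectors,
        cluster_model=cluster_model,
        extractor=extractor,
    )


@pytest.fixture()
def bare_extractor():
    """Extractor with surface templates plus the rule-based tagger only."""
    return SentenceFeatureExtractor()


@pytest.fixture()
def fig_sentence():
    """Five tokens, two single-token drug mentions."""
    return sentence_from_text(
        "luteolin and apigenin experienced extensive",
        [(0, 8, "drug"), (13, 21, "drug")],
    )
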