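import numpy as np
import pandas as pd
import pytest

from lifecourse import (
    EmbeddingConfig,
    build_sentences,
    default_cohort_spec,
    generate_cohort,
    train_embeddings,
)


@pytest.fixture(scope="session")
def small_spec():
    """Reduced planted cohort reused across module tests."""
    return default_cohort_spec(n_individuals=500, seed=7)


@pytest.fixture(scope="session")
def small_events(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_config():
    return EmbeddingConfig(dim=50, epochs=5, min_count=5, seed=7)


@pytest.fixture(scope="session")
def small_corpus(small_events, small_config):
    return build_sentences(small_events, min_count=small_config.min_count, seed=7)


@pytest.fixture(scope="session")
def small_embedding(small_corpus, small_config):
    sentences, vocab = small_corpus
    return train_embeddings(sentences, vocab, small_config)


def events_frame(rows):
    """Build an event table from (person_id, birth_year, year, code, system) rows."""
    return pd.DataFrame(
        rows, columns=["person_id", "birth_year", "year", "code", "system"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
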