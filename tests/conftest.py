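import pytest

from sentmetrics import SimConfig, base_model_spec, build_sentence_table, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced simulated dataset shared by join/evaluation tests."""
    cfg = SimConfig(
        n_languages=2,
        n_participants_per_language=5,
        n_documents=4,
        sentences_per_document=8,
        vocabulary_size=200,
        seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_table(small_dataset):
    ds = small_dataset
    return build_sentence_table(
        ds.records,
        {"surprisal": ds.surprisal, "relevance": ds.relevance},
        ds.corpus,
        ds.frequencies,
    )
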