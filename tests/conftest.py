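import pytest

from ctstage.corpus import Document
from ctstage.ner import NerConfig
from ctstage.rc import RcConfig
from ctstage.synthetic import GeneratorConfig, generate_corpus


def desk_ner_config(**overrides) -> NerConfig:
    """Small dimensions tuned for CPU-only test runs."""
    kwargs = dict(
        char_embedding_dim=24,
        seg_embedding_dim=8,
        hidden_units=32,
        dropout_rate=0.3,
        learning_rate=0.01,
        batch_size=32,
        max_epochs=10,
        early_stopping_patience=3,
        seed=0,
    )
    kwargs.update(overrides)
    return NerConfig(**kwargs)


def desk_rc_config(**overrides) -> RcConfig:
    kwargs = dict(
        embedding_dim=24,
        hidden_units=32,
        attention_dim=16,
        dropout_rate=0.3,
        learning_rate=0.01,
        batch_size=32,
        max_epochs=10,
        early_stopping_patience=3,
        seed=0,
    )
    kwargs.update(overrides)
    return RcConfig(**kwargs)


@pytest.fixture(scope="session")
def corpus200():
    """200 generated reports with scenarios and oracle answers (seed 1234)."""
    return generate_corpus(GeneratorConfig(n_reports=200, seed=1234))


@pytest.fixture(scope="session")
def docs200(corpus200) -> list[Document]:
    return [g.document for g in corpus200]


@pytest.fixture(scope="session")
def corpus60():
    """Smaller corpus for training-time-sensitive tests."""
    return generate_corpus(GeneratorConfig(n_reports=60, seed=77))
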