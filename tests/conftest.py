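import numpy as np
import pytest

from vigitext import classify
from vigitext.synthetic import SyntheticConfig, generate_corpus


@pytest.fixture(scope="session")
def default_corpus_10k():
    """One 10,000-message corpus at default generator settings."""
    cfg = SyntheticConfig(n_messages=10_000, seed=2024)
    messages, records = generate_corpus(cfg)
    return cfg, messages, records


@pytest.fixture(scope="session")
def labeled_corpus_5k():
    """5,000 labelled examples for classifier-protocol tests."""
    cfg = SyntheticConfig(n_messages=5_000, seed=7)
    messages, records = generate_corpus(cfg)
    return classify.examples_from_corpus(messages, records)


@pytest.fixture(scope="session")
def label_matrix_10k(default_corpus_10k):
    _, _, records = default_corpus_10k
    return np.stack([r.true_labels for r in records])


@pytest.fixture(scope="session")
def ae_counts_10k(label_matrix_10k):
    return label_matrix_10k.sum(axis=1)
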