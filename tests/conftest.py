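import pytest

from smokereg import make_training_corpus, train


@pytest.fixture(scope="session")
def trained_model():
    """A classifier trained on unambiguous synthetic phrasings, shared across
    tests that need a working status model."""
    examples = make_training_corpus(80, seed=20160401)
    return train(examples, seed=20160401)
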