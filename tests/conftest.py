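import numpy as np
import pytest

from mfocnn.synthetic import generate_corpus


@pytest.fixture(scope="session")
def mini_corpus():
    """5 subsets x 2 segments x 4097 samples — the smallest full-shape corpus."""
    return generate_corpus(n_segments=2, seed=11)


@pytest.fixture(scope="session")
def mini_dataset(mini_corpus):
    return mini_corpus.to_windowed()


@pytest.fixture(scope="session")
def small_two_class():
    """A-vs-E windowed data, small enough for fast training tests."""
    from mfocnn.windowing import subset_selector

    corpus = generate_corpus(n_segments=6, seed=5)
    ds = corpus.to_windowed()
    return subset_selector(ds, "A vs E")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
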