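import numpy as np
import pytest

from seqmem import PatternSequence, generate_binary_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_binary_seq():
    """A well-conditioned 8-pattern binary sequence in 12 dimensions."""
    return generate_binary_sequence(12, 8, seed=7)


@pytest.fixture
def tiny_real_seq(rng):
    return PatternSequence(rng.normal(size=(5, 6)), "real")
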