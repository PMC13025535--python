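import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture
def primes():
    """The nine-prime worked example."""
    return np.array([2.0, 3.0, 5.0, 7.0, 11.0, 17.0, 19.0, 23.0, 29.0])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
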