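import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_point_sets():
    """A batch of random continuous point sets of assorted sizes."""
    gen = np.random.default_rng(987)
    sets = []
    for size in (3, 5, 8, 12, 20, 35, 60, 120, 200):
        sets.append(gen.random((size, 2)) * 10.0)
    return sets
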