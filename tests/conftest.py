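import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_nodes(rng):
    """A small node set with well-separated descriptors."""
    vals = rng.normal(0.0, 1.0, (6, 2))
    vals[:, 1] = vals[:, 0] + np.abs(vals[:, 1])  # max >= mean per row
    return vals
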