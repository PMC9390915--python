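import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_vectors(rng):
    from sparserank.connectivity import draw_connectivity_vectors

    return draw_connectivity_vectors(300, sigma2=16.0, sigma_mn=1.44, rng=rng)
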