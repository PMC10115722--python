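import numpy as np
import pytest
from hypothesis import settings

from tlirt import QuadratureGrid

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def grid():
    """Default latent grid: 49 nodes on [-6, 6], standard normal weights."""
    return QuadratureGrid.normal()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
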