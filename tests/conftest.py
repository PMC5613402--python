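import numpy as np
import pytest
from hypothesis import settings

from grusynth.network import init_params

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_params():
    """A small random model (S_D=8, H_D=4) for fast forward/backward tests."""
    return init_params(8, 4, seed=0)
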