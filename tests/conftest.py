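import numpy as np
import pytest

from normsim import SimulationParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """A quick-to-run parameter set for structural tests."""
    return SimulationParams(n_agents=20, t_max=10, seed=7)
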