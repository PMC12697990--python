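import numpy as np
import pytest

from vertlearn import SimParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """A fast, fully valid configuration for unit-level simulation runs."""
    return SimParams(N=10, burn_in_steps=200, run_steps=200, seed=7, reps=1,
                     p_env=0.05)
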