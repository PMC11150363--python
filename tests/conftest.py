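import numpy as np
import pytest

from brainage import PhantomParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def quiet_params():
    """Noise-free, bias-free phantom parameters for geometry-level checks."""
    return PhantomParams(noise_sd=0.0, bias_amplitude=0.0)
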