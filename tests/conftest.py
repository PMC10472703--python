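import numpy as np
import pytest

from ergflux.synth import ERGSimParams, simulate_erg_epoch


@pytest.fixture
def clean_params() -> ERGSimParams:
    """Noise-free simulator defaults: exact ground truth everywhere."""
    return ERGSimParams(noise_sd=0.0)


@pytest.fixture
def clean_epoch(clean_params):
    """Noise-free epoch at the OP recording intensity (+0.3 log cd*s/m^2)."""
    return simulate_erg_epoch(clean_params, 0.3, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(20230901)
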