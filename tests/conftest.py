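import numpy as np
import pytest

from uncflow import synthetic


@pytest.fixture(scope="session")
def sensor_model():
    return synthetic.make_sensor_model(n_channels=30, n_sources=20, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def stable_var2() -> synthetic.CouplingSpec:
    """Small 2-region VAR(1) used across tests."""
    A = np.array([[[0.5, 0.0], [0.4, 0.5]]])
    return synthetic.CouplingSpec(M=2, p=1, A=A, noise_sd=1.0)
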