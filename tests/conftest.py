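import numpy as np
import pytest

from ca1prm import (ModelParams, SimConfig, WeightSet, reference_weights,
                    simulate, spectral_summary)


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def reference_model() -> ModelParams:
    """Default cell parameters with the shipped reference weight set."""
    return ModelParams().with_weights(reference_weights())


@pytest.fixture(scope="session")
def reference_trace(reference_model):
    """Baseline 8 s simulation of the reference model (computed once)."""
    return simulate(reference_model, config=SimConfig())


@pytest.fixture(scope="session")
def reference_summary(reference_trace):
    return spectral_summary(reference_trace, SimConfig())


@pytest.fixture(scope="session")
def reference_powers(reference_summary):
    """(theta, gamma) baseline peak powers of the reference set."""
    return (reference_summary.theta_power, reference_summary.gamma_power)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
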