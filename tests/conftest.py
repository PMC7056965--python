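import numpy as np
import pytest

from platecurve.fitting import NAMED_MODELS
from platecurve.synth import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_sim():
    """A quiet 2-run 96-well experiment small enough for parser tests."""
    return simulate_experiment(SimConfig(seed=11, n_runs=2, n_cycles=24, noise_sd=0.005))


@pytest.fixture(scope="session")
def noiseless_sim():
    """Noise-free full-length sim: fits must recover the truth table."""
    return simulate_experiment(
        SimConfig(seed=7, n_runs=1, n_cycles=94, noise_sd=0.0, baseline=0.0)
    )


@pytest.fixture
def gompertz_curve():
    """Noiseless Gompertz samples with A=1, mu=0.01, lambda=100."""
    x = np.linspace(0.0, 2000.0, 200)
    y = NAMED_MODELS["gompertz"]["fn"](x, 1.0, 0.01, 100.0)
    return x, y
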