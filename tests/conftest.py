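import numpy as np
import pytest

from mrbscan import ExperimentConfig, generate_experiment


@pytest.fixture(scope="session")
def noiseless_experiment():
    """Single-concentration noiseless experiment with the default signature."""
    cfg = ExperimentConfig(noise_sd=0.0, concentrations_mM=(10.0,), seed=0)
    return generate_experiment(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
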