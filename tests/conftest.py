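import numpy as np
import pytest

from gaitagree import simulate as sim
from gaitagree.model import AccelerometerAgreement


def noiseless_models(criterion_offset: float = 0.0):
    """Identity-calibration sensor models (no noise, no quantization)."""
    sparse = sim.default_sparse_model(noise_sd=0.0, quantization_step=0.0)
    criterion = sim.default_criterion_model(noise_sd=0.0,
                                            clock_offset=criterion_offset)
    return sparse, criterion


@pytest.fixture(scope="session")
def zero_jitter_config():
    return sim.SimulationConfig(stride_frequency=110.0 / 120.0,
                                cycle_jitter_sd=0.0,
                                amplitude_jitter_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def default_trial():
    """One default-condition paired trial (jitter, noise, quantization)."""
    return sim.make_paired_trial(sim.SimulationConfig(seed=21))


@pytest.fixture(scope="session")
def fitted_default(default_trial):
    sparse, criterion, truth = default_trial
    results = AccelerometerAgreement(sparse, criterion, n_boot=500).fit()
    return results, truth
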