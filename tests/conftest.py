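import numpy as np
import pytest

from rumen_observer import rusitec_preset, sample_measurements, simulate_ground_truth


@pytest.fixture(scope="session")
def rusitec_dataset():
    """Default RUSITEC-style ground truth on a moderately dense grid."""
    return simulate_ground_truth(rusitec_preset(dense_dt=0.05))


@pytest.fixture(scope="session")
def fine_dataset():
    """Finer grid for checks that compare against the ODE solution itself."""
    return simulate_ground_truth(rusitec_preset(dense_dt=0.02))


@pytest.fixture(scope="session")
def noiseless_samples(rusitec_dataset):
    """Exact (noise-free) proxy + VFA samples on the RUSITEC schedule."""
    return sample_measurements(rusitec_dataset, noise_sd_proxy=0.0, noise_sd_vfa=0.0, seed=1)
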