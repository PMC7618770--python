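import numpy as np
import pytest

from evuptake import simulate


@pytest.fixture
def noiseless_config():
    """Deterministic rendering: no noise, no texture."""
    return simulate.SimulationConfig(
        read_noise_sd=0.0, shot_noise_scale=0.0, heterogeneity_amplitude=0.0, seed=0
    )


@pytest.fixture
def noiseless_field(noiseless_config):
    return simulate.simulate_myocyte_field(noiseless_config)


def iou(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    return float(np.logical_and(a, b).sum() / union) if union else 0.0
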