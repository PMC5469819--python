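import pytest

from stopover_pace.config import SimulationConfig
from stopover_pace.simulate import simulate_dataset


@pytest.fixture(scope="session")
def mid_dataset():
    """One moderately sized synthetic season shared across tests."""
    return simulate_dataset(SimulationConfig(n_birds=400, rng_seed=11))


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free telemetry: no false positives, no envelope noise."""
    cfg = SimulationConfig(
        n_birds=250, rng_seed=5, false_positive_rate=0.0, envelope_noise_sd=0.0
    )
    return simulate_dataset(cfg)
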