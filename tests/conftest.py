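import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from prevoid.echo_sim import SimulationConfig, default_volunteers, simulate_protocol_dataset
from prevoid.features import GateConfig

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def volunteers():
    return default_volunteers()


@pytest.fixture(scope="session")
def noiseless_config():
    return SimulationConfig(noise_sd=0.0, speckle_sd=0.0)


@pytest.fixture(scope="session")
def gates():
    return GateConfig()


@pytest.fixture(scope="session")
def small_dataset(volunteers):
    """One short day per wearer: 4 acquisitions × 10 traces, low noise."""
    cfg = SimulationConfig(noise_sd=0.02, speckle_sd=0.02)
    v1, v2 = volunteers
    d1 = simulate_protocol_dataset(
        cfg, v1, n_days=1, session_duration_min=160, interval_min=40,
        samples_per_acquisition=10, seed=101,
    )
    d2 = simulate_protocol_dataset(
        cfg, v2, n_days=1, session_duration_min=160, interval_min=40,
        samples_per_acquisition=10, seed=102,
    )
    return pd.concat([d1.features, d2.features], ignore_index=True)


@pytest.fixture(scope="session")
def protocol_2x5(volunteers):
    """The reference-scale study: two wearers, five days each, noise 0.05."""
    cfg = SimulationConfig(noise_sd=0.05)
    v1, v2 = volunteers
    d1 = simulate_protocol_dataset(cfg, v1, n_days=5, seed=11)
    d2 = simulate_protocol_dataset(cfg, v2, n_days=5, seed=12)
    return pd.concat([d1.features, d2.features], ignore_index=True)
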