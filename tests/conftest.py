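import numpy as np
import pytest

from turnsig import RunConfig, SimConfig, make_trial


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def run_config():
    return RunConfig()


def _clean_sim_config(**overrides) -> SimConfig:
    """Noise-free, oscillation-free study conditions: the pipeline input is
    exactly the analytic signature riding on the trunk yaw ramp."""
    base = dict(
        noise={"orientation_deg": 0.0, "accel": 0.0, "gyro": 0.0},
        gait={"roll_amp_deg": 0.0, "pitch_amp_deg": 0.0},
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture
def clean_sim_config():
    return _clean_sim_config()


@pytest.fixture
def clean_trial(clean_sim_config):
    return make_trial(clean_sim_config, seed=42)


@pytest.fixture
def noisy_trial():
    return make_trial(SimConfig(), seed=42)


@pytest.fixture
def clean_config_factory():
    return _clean_sim_config
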