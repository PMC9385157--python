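import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully featured simulated session shared across tests."""
    from shellmea import SimConfig, generate_recording

    cfg = SimConfig(
        duration_s=10.0,
        n_rounds=2,
        spike_rate_hz=3.0,
        seed=101,
    )
    rec, gt = generate_recording(cfg)
    return cfg, rec, gt
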