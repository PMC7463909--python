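import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_intact():
    """A small intact-regime recording with ground truth, shared across tests."""
    import calcinet as cn

    cfg = cn.apply_regime("intact", seed=42, n_cells=30, duration=300.0)
    recording, truth = cn.simulate_recording(cfg, group_label="intact")
    return cfg, recording, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
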