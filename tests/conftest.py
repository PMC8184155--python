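import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def mini_ring():
    """Miniature ring config (64 pyr / 16 int) for fast structural tests."""
    from ringdpx.synthetic import mini_ring_config

    return mini_ring_config()


@pytest.fixture(scope="session")
def mini_trials(mini_ring):
    """Two short seeded trials of the miniature ring with a cue stimulus."""
    from ringdpx.ring_network import StimulusSpec, run_ring_batch

    stim = StimulusSpec(np.pi / 2, 100.0, 400.0, 0.9)
    ss = np.random.SeedSequence(2024)
    return run_ring_batch(mini_ring, [stim], 600.0, ss.spawn(2))
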