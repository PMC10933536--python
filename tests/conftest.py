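import numpy as np
import pytest

from callerid.simulate import SimConfig, simulate_scene


@pytest.fixture(scope="session")
def detection_scene():
    """A small 2-whale detection-level scene with ground truth."""
    cfg = SimConfig(n_whales=2, duration=900.0, spacing_mean=100.0, seed=42)
    return simulate_scene(cfg, waveform=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
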