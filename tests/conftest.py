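import numpy as np
import pytest

from tcsleep.engine import SimConfig, run_simulation


@pytest.fixture(scope="session")
def control_recording():
    """Shared short Control run used by engine/network/analysis tests."""
    cfg = SimConfig(duration=12.0, seed=11, record_th=(20, 60))
    return run_simulation(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
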