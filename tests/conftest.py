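import numpy as np
import pytest

from remhf import SimulationConfig, simulate_hypnogram, simulate_signals, inject_artifacts


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """30-minute two-channel simulation used by several unit tests."""
    return SimulationConfig(duration_hours=0.5, channels=("eeg_v1", "emg"), seed=11)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """(recording-with-artifacts, hypnogram, artifact_times) at 30 min."""
    hyp = simulate_hypnogram(small_cfg)
    rec = simulate_signals(hyp, small_cfg)
    rec, times = inject_artifacts(rec, hyp, small_cfg)
    return rec, hyp, times


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230613)
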