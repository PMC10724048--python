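import numpy as np
import pytest

from gaitersp.config import ProcessingConfig, SimulationConfig
from gaitersp.experiments import ROI_ONLY_CHANNELS
from gaitersp.simulate import simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def tiny_config(**overrides) -> SimulationConfig:
    """Two subjects per group, few trials, ROI-only montage: fast but complete."""
    base = dict(
        n_per_group=2, n_trials=9, n_blocks=3, sampling_rate=128.0,
        channel_labels=ROI_ONLY_CHANNELS, seed=77,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture
def tiny_cfg():
    return tiny_config()


@pytest.fixture(scope="session")
def tiny_cohort():
    return simulate_cohort(tiny_config())


@pytest.fixture
def fast_proc():
    return ProcessingConfig(fstep=2.0, decim=6)
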