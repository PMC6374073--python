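import numpy as np
import pytest

from zfcereb.synth import (GeneratorConfig, make_protocol, simulate_behavior,
                           simulate_purkinje)


@pytest.fixture(scope="session")
def config():
    """Small default session (2 stimulus + 1 blank trial) for fast tests."""
    return GeneratorConfig(seed=42, n_trials=2, n_blank_trials=1)


@pytest.fixture(scope="session")
def protocol(config):
    return make_protocol(config)


@pytest.fixture(scope="session")
def behavior_sim(config, protocol):
    return simulate_behavior(protocol, config)


@pytest.fixture(scope="session")
def motion_onset_cell(config, protocol, behavior_sim):
    return simulate_purkinje(protocol, behavior_sim, "motion_onset", config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
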