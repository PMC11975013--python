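import logging

import pytest

from isofinger import SimulationConfig, simulate_study

logging.getLogger("isofinger").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def default_study(default_config):
    return simulate_study(default_config)
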