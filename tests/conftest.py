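import logging

import numpy as np
import pytest

import oceanmix as om

logging.getLogger("oceanmix").setLevel(logging.ERROR)
logging.getLogger("oceanmix.index").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def toy_scenario():
    return om.default_scenario("toy", seed=11)


@pytest.fixture(scope="session")
def toy_data(toy_scenario):
    bundle, truth = om.simulate_dataset(toy_scenario)
    return bundle, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
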