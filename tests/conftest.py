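import numpy as np
import pytest

from epilayout import (
    Weights,
    build_forearm_model,
    default_measurements,
    default_template,
)


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture(scope="session")
def measurements():
    return default_measurements()


@pytest.fixture(scope="session")
def model(template, measurements):
    return build_forearm_model(measurements, template)


@pytest.fixture(scope="session")
def uni_muscles():
    return ("FCR", "BR", "PL")


@pytest.fixture(scope="session")
def uni_weights():
    return Weights(emg=1.0, area=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
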