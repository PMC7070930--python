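import numpy as np
import pytest

from mta import deconvolve, make_scenario


@pytest.fixture(scope="session")
def default_bundle():
    return make_scenario("indomethacin_default", 1)


@pytest.fixture(scope="session")
def default_measurement(default_bundle):
    return default_bundle.simulate()


@pytest.fixture(scope="session")
def default_deconv(default_measurement):
    return deconvolve(default_measurement, "1", P=20.0)


@pytest.fixture(scope="session")
def movie_temps():
    """Frame temperatures: 30 -> 70 degC every 0.5 degC (one frame per ~18.75 s)."""
    return np.arange(30.0, 70.01, 0.5)
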