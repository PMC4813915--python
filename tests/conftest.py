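import numpy as np
import pytest

from ricescale import CropParams, generate_meteo, simulate
from ricescale.meteo import MeteoSeries

OBS_DATES = (166, 199, 240)


@pytest.fixture(scope="session")
def meteo():
    return generate_meteo(seed=1)


@pytest.fixture(scope="session")
def params():
    return CropParams()


@pytest.fixture(scope="session")
def stressed_traj(params, meteo):
    """Reference stressed season run shared across tests."""
    return simulate(params, meteo, (0.85, 0.9))


@pytest.fixture(scope="session")
def constant_meteo():
    """Noise-free weather: constant 28 degC, 18 MJ radiation."""
    doy = np.arange(1, 366)
    return MeteoSeries(doy, np.full(365, 24.0), np.full(365, 32.0),
                       np.full(365, 18.0))
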