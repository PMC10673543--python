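import numpy as np
import pytest

from acidocest.bmsim import default_background_pools, water_pool
from acidocest.calibration import IopamidolModel, build_pipeline_calibration
from acidocest.phantom import default_protocol


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def model():
    return IopamidolModel()


@pytest.fixture(scope="session")
def background():
    return default_background_pools()


@pytest.fixture(scope="session")
def water():
    return water_pool()


@pytest.fixture(scope="session")
def curve(model, protocol, background):
    """Default measurement-consistent calibration curve, shared per session."""
    return build_pipeline_calibration(
        model, protocol, np.arange(6.0, 7.4001, 0.05), background=background
    )
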