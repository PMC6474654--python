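import numpy as np
import pytest

from scrval.landscape import build_grids, generate_habitat
from scrval.observation import DetectionParameters


@pytest.fixture(scope="session")
def default_grids():
    return build_grids()


@pytest.fixture(scope="session")
def habitat_landscape(default_grids):
    landscape, _ = default_grids
    return generate_habitat(landscape, seed=20190419)


@pytest.fixture(scope="session")
def truth_params():
    return DetectionParameters()
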