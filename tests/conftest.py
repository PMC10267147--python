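import numpy as np
import pytest

from kirchnet import (
    CellGeometry,
    MitchellSchaeffer,
    PassiveMembrane,
    TissueParams,
    build_grid_network,
)


@pytest.fixture
def geom():
    return CellGeometry()


@pytest.fixture
def params():
    return TissueParams()


@pytest.fixture
def strand15(geom, params):
    return build_grid_network(15, 1, geom, params)


@pytest.fixture
def passive():
    return PassiveMembrane()


@pytest.fixture
def excitable():
    return MitchellSchaeffer()


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
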