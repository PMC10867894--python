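import numpy as np
import pytest

from pecsim.system import Model
from pecsim.units import DEFAULT_UNITS, bjerrum_from_permittivity

LB_PEC = DEFAULT_UNITS.to_reduced_length(bjerrum_from_permittivity(62.0))
LB_SUP = DEFAULT_UNITS.to_reduced_length(bjerrum_from_permittivity(78.0))


@pytest.fixture(scope="session")
def model() -> Model:
    return Model.default()

@pytest.fixture(scope="session")
def neutral_model() -> Model:
    return Model.default(electrostatics=False)


@pytest.fixture(scope="session")
def ideal_model() -> Model:
    return Model.ideal()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
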