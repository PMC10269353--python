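import numpy as np
import pytest

from smirkfit.chem_model import assign_parameters
from smirkfit.synthetic_data import (
    default_molecule_set,
    make_alkane,
    make_amide,
    toy_forcefield,
)


@pytest.fixture(scope="session")
def toy_ff():
    return toy_forcefield()


@pytest.fixture(scope="session")
def molecules():
    return default_molecule_set(seed=0)


@pytest.fixture(scope="session")
def assignments(molecules, toy_ff):
    return {m.name: assign_parameters(m, toy_ff) for m in molecules}


@pytest.fixture(scope="session")
def butane():
    return make_alkane(4)


@pytest.fixture(scope="session")
def amide():
    return make_amide()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
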