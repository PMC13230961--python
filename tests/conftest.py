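import numpy as np
import pytest

from cscrit import (
    DoseSchedule,
    LQParams,
    OERParams,
    OxygenFieldParams,
    PressureField,
    builtin_registry,
    effective_times,
)

RADIONUCLIDES = ("90Y", "131I", "177Lu", "225Ac")


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()


@pytest.fixture(scope="session")
def lq():
    return LQParams()


@pytest.fixture(scope="session")
def oer_params():
    return OERParams()


@pytest.fixture
def schedule():
    def make(name: str, r0: float = 2.0) -> DoseSchedule:
        return DoseSchedule.for_radionuclide(name, r0)

    return make


@pytest.fixture
def uniform_oxygen_field():
    """Uniform 40 mmHg field on the full 101x101 grid, density 1 cell/mm^3."""
    params = OxygenFieldParams(cell_density=1.0)
    n = params.n_nodes
    return PressureField(P=np.full((n, n), 40.0), t=0.0, params=params)
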