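import pytest

from pumpleak import (
    CellState,
    Medium,
    TransportParams,
    solve_potential,
)
from pumpleak.scenarios import (
    NACL100_MEDIUM,
    NORMAL_MEDIUM,
    SUCROSE180_MEDIUM,
    U937_MEASUREMENT,
    reference_params,
    reference_state,
)


@pytest.fixture(scope="session")
def normal_medium() -> Medium:
    return NORMAL_MEDIUM


@pytest.fixture(scope="session")
def nacl_medium() -> Medium:
    return NACL100_MEDIUM


@pytest.fixture(scope="session")
def sucrose_medium() -> Medium:
    return SUCROSE180_MEDIUM


@pytest.fixture(scope="session")
def measurement():
    return U937_MEASUREMENT


@pytest.fixture(scope="session")
def resting_state() -> CellState:
    return reference_state()


@pytest.fixture(scope="session")
def full_params() -> TransportParams:
    """Full NC+KC+NKCC parameter set, permeabilities fitted at U = -45.0 mV."""
    return reference_params("NC+KC+NKCC")


@pytest.fixture(scope="session")
def printed_full_params() -> TransportParams:
    """Full set with the published 2-3 significant figure permeabilities."""
    return reference_params("NC+KC+NKCC", fitted=False)


@pytest.fixture(scope="session")
def resting_u(resting_state, full_params, normal_medium) -> float:
    return solve_potential(resting_state, full_params, normal_medium).u
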