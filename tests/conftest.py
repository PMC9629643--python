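import numpy as np
import pytest

from pcls_oxygen import (
    SurfaceOxygen,
    TransportParams,
    default_parameters,
    solve_oxygen_field,
)

PHI0_ATM = 160.0


@pytest.fixture(scope="session")
def default_5mm():
    """Reference 5 mm-slice configuration, middle placement."""
    system, transport = default_parameters()
    return system, transport


@pytest.fixture(scope="session")
def surface_atm():
    return SurfaceOxygen.from_fraction(0.21)


@pytest.fixture(scope="session")
def transport_inert():
    """Uniform-media limit: equal diffusivities, no uptake."""
    return TransportParams(d_media=1.6e-9, d_tissue=1.6e-9, uptake_rate=0.0)


@pytest.fixture(scope="session")
def sol7_middle5(default_5mm, surface_atm):
    system, transport = default_5mm
    return solve_oxygen_field(system, transport, surface_atm, M=7)


@pytest.fixture(scope="session")
def sol40_middle5(default_5mm, surface_atm):
    system, transport = default_5mm
    return solve_oxygen_field(system, transport, surface_atm, M=40)


@pytest.fixture(scope="session")
def fd200_middle5(default_5mm, surface_atm):
    from pcls_oxygen import solve_fd

    system, transport = default_5mm
    return solve_fd(system, transport, surface_atm, n_r=200, n_z=200)
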