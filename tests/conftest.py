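import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from umbraflux.geometry import EclipseGeometry
from umbraflux.synthetic import (
    ForcingParams,
    LeafSimParams,
    generate_forcing,
    generate_gas_exchange,
    generate_water_potentials,
)


@pytest.fixture(scope="session")
def geometry() -> EclipseGeometry:
    return EclipseGeometry()


@pytest.fixture(scope="session")
def default_forcing(geometry):
    """Zero-noise eclipse-day forcing at the default calibration."""
    return generate_forcing(ForcingParams(), geometry)


@pytest.fixture(scope="session")
def leaf_params() -> LeafSimParams:
    return LeafSimParams()


@pytest.fixture(scope="session")
def default_leaf(default_forcing, leaf_params):
    """Zero-noise 30-s gas-exchange and fluorescence series."""
    return generate_gas_exchange(default_forcing, leaf_params)


@pytest.fixture(scope="session")
def default_water(default_leaf, leaf_params):
    gas, _ = default_leaf
    return generate_water_potentials(gas, leaf_params)


@pytest.fixture(scope="session")
def totality_mask(default_leaf, geometry):
    gas, _ = default_leaf
    t = gas.time.to_numpy().astype("datetime64[ns]")
    return (t >= np.datetime64(geometry.c2_time)) & (
        t <= np.datetime64(geometry.c3_time)
    )
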