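import numpy as np
import pytest

from agroens.crop import maize_genotype, wheat_genotype
from agroens.management import ManagementPlan
from agroens.soil import SoilGrid, SoilHorizon, SoilProfile, load_soil_fixture, make_grid
from agroens.synthetic import default_climatology, generate_weather


@pytest.fixture(scope="session")
def adet_weather():
    """Three years of synthetic weather at the unimodal-rainfall site."""
    return generate_weather(default_climatology("Adet"), 3, seed=7)


@pytest.fixture(scope="session")
def adet_grid():
    return make_grid(load_soil_fixture("Adet"))


@pytest.fixture(scope="session")
def mgmt():
    return ManagementPlan()


@pytest.fixture(scope="session")
def wheat():
    return wheat_genotype()


@pytest.fixture(scope="session")
def maize():
    return maize_genotype()


@pytest.fixture(scope="session")
def sandy_grid():
    """Single-horizon coarse-texture profile for Richards/bucket contrasts."""
    profile = SoilProfile("sandbox", [
        SoilHorizon(0, 30, 10, 8, 1.50, 6.5, 0.8, 6.0, 16.0, 10),
        SoilHorizon(30, 60, 10, 8, 1.55, 6.5, 0.5, 6.0, 16.0, 10),
        SoilHorizon(60, 100, 10, 8, 1.60, 6.5, 0.3, 6.0, 15.0, 10),
    ])
    return make_grid(profile)


@pytest.fixture(scope="session")
def n_poor_grid():
    """Low organic carbon profile: crop growth there is N-limited."""
    profile = SoilProfile("n_poor", [
        SoilHorizon(0, 30, 30, 30, 1.35, 6.5, 0.15, 12.0, 26.0, 20),
        SoilHorizon(30, 60, 30, 32, 1.40, 6.5, 0.10, 12.0, 25.0, 20),
        SoilHorizon(60, 100, 30, 33, 1.45, 6.5, 0.05, 12.0, 24.0, 20),
    ])
    return make_grid(profile)
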