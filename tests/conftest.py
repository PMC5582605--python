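import numpy as np
import pytest

from kdtli import (
    InterferometerGeometry,
    LaserSettings,
    MoleculeSpec,
    make_velocity_distribution,
)


@pytest.fixture(scope="session")
def geometry():
    return InterferometerGeometry()


@pytest.fixture(scope="session")
def laser():
    return LaserSettings(power_W=6.0)


@pytest.fixture(scope="session")
def tocopherol():
    # vitamin E: experimental optical polarizability and susceptibility
    return MoleculeSpec.from_formula(
        "alpha-tocopherol", "C29H50O2",
        alpha_opt_A3=58.0, sigma_abs_m2=0.0, alpha_stat_A3=54.0,
        mu_debye=1.8, chi_A3=80.0, temperature_K=400.0,
    )


@pytest.fixture(scope="session")
def phylloquinone():
    return MoleculeSpec.from_formula(
        "phylloquinone", "C31H46O2",
        alpha_opt_A3=52.0, sigma_abs_m2=0.0, alpha_stat_A3=58.0,
        mu_debye=1.1, chi_A3=80.0, temperature_K=450.0,
    )


@pytest.fixture(scope="session")
def carotene():
    # provitamin A: the experiment measures |alpha_opt| = 83 A^3
    return MoleculeSpec.from_formula(
        "beta-carotene", "C40H56",
        alpha_opt_A3=83.0, sigma_abs_m2=0.0, alpha_stat_A3=211.0,
        mu_debye=1.3, chi_A3=229.0, temperature_K=460.0,
    )


@pytest.fixture(scope="session")
def beam200():
    return make_velocity_distribution(200.0, 0.45)


@pytest.fixture(scope="session")
def beam180():
    return make_velocity_distribution(180.0, 0.45)


@pytest.fixture(scope="session")
def c60():
    """Calibration reference species with known electronic properties."""
    return MoleculeSpec(
        name="C60", mass_amu=720.66, alpha_opt_A3=85.0,
        sigma_abs_m2=0.0, chi_A3=89.0,
    )
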