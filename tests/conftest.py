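import numpy as np
import pytest

from arfsim.fields import StandingWaveSpec
from arfsim.materials import NIH3T3, WATER, FluidProperties
from arfsim.radforce import ScatteringCoefficients

WAVELENGTH = 60.0e-6
PEAK_PRESSURE = 2.0e5


@pytest.fixture(scope="session")
def water():
    """Tabulated water (compressibility as printed, 4 significant figures)."""
    return WATER


@pytest.fixture(scope="session")
def water_exact():
    """Water with compressibility derived exactly as 1/(rho c^2).

    The tabulated beta is rounded to 4 significant figures; closed-form
    identities that rely on beta = 1/(rho c^2) exactly (energy-density
    factorisation, equipartition) are checked against this variant.
    """
    return FluidProperties(density=1.0e3, sound_speed=1.502e3, shear_viscosity=8.538e-4)


@pytest.fixture(scope="session")
def cell():
    return NIH3T3


@pytest.fixture(scope="session")
def coeffs(cell, water):
    return ScatteringCoefficients.from_materials(cell, water)


@pytest.fixture(scope="session")
def coeffs_exact(cell, water_exact):
    return ScatteringCoefficients.from_materials(cell, water_exact)


@pytest.fixture(scope="session")
def spec_1d(water):
    """One-directional standing wave along y: p = p_ac cos(ky)."""
    return StandingWaveSpec.one_dimensional(WAVELENGTH, PEAK_PRESSURE, water)


@pytest.fixture(scope="session")
def spec_1d_exact(water_exact):
    return StandingWaveSpec.one_dimensional(WAVELENGTH, PEAK_PRESSURE, water_exact)


@pytest.fixture(scope="session")
def spec_2d(water):
    """Two equal perpendicular components, mutually in phase (node lattice)."""
    return StandingWaveSpec.perpendicular(WAVELENGTH, PEAK_PRESSURE, water)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(17)
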