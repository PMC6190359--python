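"""Material properties of host fluids and bio-particles.

Bio-particles (cells, liposomes, microvesicles, viruses) suspended in water
have acoustic properties close to those of the host fluid, which is precisely
what makes the volume-averaged radiation-force model applicable.  This module
holds the reference property sets (water at 25 °C and an NIH/3T3 fibroblast),
the standard derived-quantity formulas connecting them

    beta = 1 / (rho c^2)                      isentropic compressibility
    nu   = (3 kappa - 2 G) / (2 (3 kappa + G))  Poisson ratio, kappa = 1/beta
    c    = sqrt( [3 (1 - nu) / (1 + nu)] / (rho beta) )  longitudinal speed
    c_s  = sqrt(G / rho)                      shear (transverse) speed

and the validity diagnostics of the ideal-fluid / finite-size modelling
regime: viscous and thermal boundary-layer thicknesses and acoustic
impedance closeness.

All quantities are SI throughout; there is no unit-conversion layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigError, DomainError

__all__ = [
    "FluidProperties",
    "ParticleProperties",
    "WATER",
    "NIH3T3",
    "TABLE_WATER",
    "TABLE_NIH3T3",
    "BIOPARTICLE_PRESETS",
    "compressibility_from_speed",
    "poisson_ratio",
    "longitudinal_speed",
    "shear_speed",
    "acoustic_impedance",
    "viscous_penetration_depth",
    "thermal_penetration_depth",
    "validity_summary",
    "fluid_from_mapping",
    "particle_from_mapping",
    "fluid_to_mapping",
    "particle_to_mapping",
    "load_fluid",
    "load_particle",
    "save_materials",
]


# --------------------------------------------------------------------------
# scalar formulas
# --------------------------------------------------------------------------

def _require_positive(**values: float) -> None:
    for name, value in values.items():
        if not (value > 0.0) or not math.isfinite(value):
            raise DomainError(f"{name} must be strictly positive and finite, got {value!r}")


def compressibility_from_speed(density: float, sound_speed: float) -> float:
    """Isentropic compressibility ``1 / (rho c^2)`` in Pa^-1."""
    _require_positive(density=density, sound_speed=sound_speed)
    return 1.0 / (density * sound_speed**2)


def poisson_ratio(shear_modulus: float, bulk_modulus: float) -> float:
    """Poisson ratio ``(3 kappa - 2 G) / (2 (3 kappa + G))``.

    For soft bio-particles G is kPa-scale while kappa ~ GPa, so the result
    sits within a few 1e-7 of the incompressible limit 0.5.
    """
    if shear_modulus < 0.0:
        raise DomainError(f"shear modulus must be non-negative, got {shear_modulus!r}")
    _require_positive(bulk_modulus=bulk_modulus)
    return (3.0 * bulk_modulus - 2.0 * shear_modulus) / (
        2.0 * (3.0 * bulk_modulus + shear_modulus)
    )


def longitudinal_speed(density: float, compressibility: float, nu: float = 0.5) -> float:
    """Longitudinal (compressional) wave speed of a nearly-incompressible solid.

    ``c = sqrt( [3 (1 - nu) / (1 + nu)] / (rho beta) )``; at ``nu = 0.5`` this
    reduces to the fluid relation ``sqrt(1 / (rho beta))``.
    """
    _require_positive(density=density, compressibility=compressibility)
    if not (0.0 <= nu < 1.0):
        raise DomainError(f"Poisson ratio must lie in [0, 1), got {nu!r}")
    return math.sqrt((3.0 * (1.0 - nu) / (1.0 + nu)) / (density * compressibility))


def shear_speed(shear_modulus: float, density: float) -> float:
    """Shear (transverse) wave speed ``sqrt(G / rho)``."""
    if shear_modulus < 0.0:
        raise DomainError(f"shear modulus must be non-negative, got {shear_modulus!r}")
    _require_positive(density=density)
    return math.sqrt(shear_modulus / density)


def acoustic_impedance(density: float, sound_speed: float) -> float:
    """Specific acoustic impedance ``Z = rho c`` (Pa s m^-1)."""
    _require_positive(density=density, sound_speed=sound_speed)
    return density * sound_speed


def viscous_penetration_depth(viscosity: float, density: float, frequency: float) -> float:
    """Viscous boundary-layer thickness ``delta_v = sqrt(2 nu / omega)``.

    nu = mu/rho is the kinematic viscosity, omega = 2 pi f.  Scales as
    f^(-1/2): at MHz-and-above actuation the layer is far thinner than a
    cell, which is what justifies the ideal-fluid scattering coefficients.
    """
    _require_positive(viscosity=viscosity, density=density, frequency=frequency)
    return math.sqrt(2.0 * (viscosity / density) / (2.0 * math.pi * frequency))


def thermal_penetration_depth(
    thermal_conductivity: float, density: float, specific_heat: float, frequency: float
) -> float:
    """Thermal boundary-layer thickness ``delta_t = sqrt(2 D_th / omega)``,
    with thermal diffusivity ``D_th = k_t / (rho h_c)``."""
    _require_positive(
        thermal_conductivity=thermal_conductivity,
        density=density,
        specific_heat=specific_heat,
        frequency=frequency,
    )
    diffusivity = thermal_conductivity / (density * specific_heat)
    return math.sqrt(2.0 * diffusivity / (2.0 * math.pi * frequency))


# --------------------------------------------------------------------------
# property containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FluidProperties:
    """Host-fluid properties.

    ``compressibility`` may be omitted, in which case it is derived as
    ``1/(rho c^2)``; when both are supplied they must agree to 0.1%.
    Thermal and viscous parameters are optional — they feed only the
    validity diagnostics, not the ideal-fluid force model.
    """

    density: float
    sound_speed: float
    compressibility: float | None = None
    shear_viscosity: float | None = None
    bulk_viscosity: float | None = None
    thermal_expansion: float | None = None
    specific_heat: float | None = None
    heat_ratio: float | None = None
    thermal_conductivity: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        _require_positive(density=self.density, sound_speed=self.sound_speed)
        derived = compressibility_from_speed(self.density, self.sound_speed)
        if self.compressibility is None:
            object.__setattr__(self, "compressibility", derived)
        else:
            _require_positive(compressibility=self.compressibility)
            if abs(self.compressibility - derived) > 1.0e-3 * derived:
                raise DomainError(
                    "compressibility inconsistent with 1/(rho c^2): "
                    f"given {self.compressibility:.4e}, derived {derived:.4e}"
                )
        for attr in (
            "shear_viscosity",
            "bulk_viscosity",
            "thermal_expansion",
            "specific_heat",
            "heat_ratio",
            "thermal_conductivity",
        ):
            value = getattr(self, attr)
            if value is not None:
                _require_positive(**{attr: value})

    @property
    def impedance(self) -> float:
        return acoustic_impedance(self.density, self.sound_speed)


@dataclass(frozen=True)
class ParticleProperties:
    """Bio-particle properties: density, compressibility, shear modulus, radius.

    The diameter ``D_p = 2a`` is exact by construction.  Longitudinal and
    shear wave speeds, when not supplied, are derived from the footnote
    formulas (Poisson ratio from G and kappa = 1/beta).
    """

    density: float
    compressibility: float
    radius: float
    shear_modulus: float = 0.0
    longitudinal_speed: float | None = None
    shear_speed: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        _require_positive(
            density=self.density, compressibility=self.compressibility, radius=self.radius
        )
        if self.shear_modulus < 0.0:
            raise DomainError(f"shear modulus must be non-negative, got {self.shear_modulus!r}")
        if self.longitudinal_speed is None:
            nu = poisson_ratio(self.shear_modulus, 1.0 / self.compressibility)
            object.__setattr__(
                self,
                "longitudinal_speed",
                longitudinal_speed(self.density, self.compressibility, nu),
            )
        if self.shear_speed is None:
            object.__setattr__(
                self, "shear_speed", shear_speed(self.shear_modulus, self.density)
            )

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius**3

    @property
    def impedance(self) -> float:
        return acoustic_impedance(self.density, self.longitudinal_speed)

    def with_radius(self, radius: float) -> "ParticleProperties":
        return replace(self, radius=radius)


# --------------------------------------------------------------------------
# reference registries
# --------------------------------------------------------------------------

# Water at 25 degC, stored cell-for-cell as printed in the reference table.
TABLE_WATER: Mapping[str, float] = {
    "rho0": 1.0e3,            # kg m^-3
    "beta": 4.433e-10,        # Pa^-1, = 1/(rho c^2)
    "alpha": 2.748e-4,        # K^-1
    "h_c": 4.181e3,           # J kg^-1 K^-1
    "gamma": 1.012,           # -
    "k_t": 6.095e-1,          # W m^-1 K^-1
    "c": 1.502e3,             # m s^-1
    "mu": 8.538e-4,           # Pa s
    "mu_b": 2.4e-3,           # Pa s
}

# NIH/3T3 fibroblast.  The printed transverse-speed cell is 1.244e3 m/s,
# but the defining formula sqrt(G/rho0) with the printed G gives 1.244 m/s;
# the cell is stored verbatim and the formula is used everywhere else.
TABLE_NIH3T3: Mapping[str, float] = {
    "rho0": 1.079e3,          # kg m^-3
    "G": 1.67e3,              # Pa
    "beta": 3.78e-10,         # Pa^-1
    "alpha": 2.0e-4,          # K^-1
    "h_c": 3.421e3,           # J kg^-1 K^-1
    "gamma": 1.012,           # -
    "k_t": 4.9e-1,            # W m^-1 K^-1
    "c": 1.566e3,             # m s^-1, from the Poisson-ratio formula
    "c_s": 1.244e3,           # m s^-1, printed cell (see note above)
}

WATER = FluidProperties(
    density=TABLE_WATER["rho0"],
    sound_speed=TABLE_WATER["c"],
    compressibility=TABLE_WATER["beta"],
    shear_viscosity=TABLE_WATER["mu"],
    bulk_viscosity=TABLE_WATER["mu_b"],
    thermal_expansion=TABLE_WATER["alpha"],
    specific_heat=TABLE_WATER["h_c"],
    heat_ratio=TABLE_WATER["gamma"],
    thermal_conductivity=TABLE_WATER["k_t"],
    name="water",
)

#: NIH/3T3 cell with the commonly simulated 10 um diameter.
NIH3T3 = ParticleProperties(
    density=TABLE_NIH3T3["rho0"],
    compressibility=TABLE_NIH3T3["beta"],
    shear_modulus=TABLE_NIH3T3["G"],
    radius=5.0e-6,
    name="nih3t3",
)

#: Approximate density / longitudinal-speed presets for common bio-particle
#: classes, for illustration only (order-of-magnitude literature values; the
#: point they make is that Z_p/Z_f stays near unity for all of them).
BIOPARTICLE_PRESETS: Mapping[str, Mapping[str, float | str]] = {
    "cell": {"rho0": 1.079e3, "c": 1.566e3, "note": "approximate (NIH/3T3-like)"},
    "liposome": {"rho0": 1.01e3, "c": 1.45e3, "note": "approximate"},
    "microvesicle": {"rho0": 1.04e3, "c": 1.48e3, "note": "approximate"},
    "virus": {"rho0": 1.15e3, "c": 1.60e3, "note": "approximate"},
}


def validity_summary(
    fluid: FluidProperties, particle: ParticleProperties, frequency: float
) -> dict[str, float]:
    """Diagnostics of the modelling regime at a given actuation frequency.

    Returns the viscous/thermal boundary-layer thicknesses (requires the
    fluid's viscous/thermal parameters), the size parameter ka, and the
    particle-to-fluid impedance ratio.  The finite-size model assumes
    delta_v, delta_t << a and Z_p/Z_f near 1.
    """
    _require_positive(frequency=frequency)
    wavelength = fluid.sound_speed / frequency
    out = {
        "frequency_hz": frequency,
        "wavelength_m": wavelength,
        "ka": 2.0 * math.pi / wavelength * particle.radius,
        "dp_over_lambda": particle.diameter / wavelength,
        "impedance_ratio": particle.impedance / fluid.impedance,
    }
    if fluid.shear_viscosity is not None:
        out["viscous_depth_m"] = viscous_penetration_depth(
            fluid.shear_viscosity, fluid.density, frequency
        )
        out["viscous_depth_over_radius"] = out["viscous_depth_m"] / particle.radius
    if fluid.thermal_conductivity is not None and fluid.specific_heat is not None:
        out["thermal_depth_m"] = thermal_penetration_depth(
            fluid.thermal_conductivity, fluid.density, fluid.specific_heat, frequency
        )
        out["thermal_depth_over_radius"] = out["thermal_depth_m"] / particle.radius
    return out


# --------------------------------------------------------------------------
# YAML mappings (keys follow the property-table symbols)
# --------------------------------------------------------------------------

_FLUID_KEYS = {
    "rho0": "density",
    "c": "sound_speed",
    "beta": "compressibility",
    "mu": "shear_viscosity",
    "mu_b": "bulk_viscosity",
    "alpha": "thermal_expansion",
    "h_c": "specific_heat",
    "gamma": "heat_ratio",
    "k_t": "thermal_conductivity",
    "name": "name",
}

_PARTICLE_KEYS = {
    "rho0": "density",
    "beta": "compressibility",
    "G": "shear_modulus",
    "a": "radius",
    "c": "longitudinal_speed",
    "c_s": "shear_speed",
    "name": "name",
}


def _from_mapping(mapping: Mapping[str, object], keys: Mapping[str, str], cls, what: str):
    unknown = sorted(set(mapping) - set(keys))
    if unknown:
        raise ConfigError(f"{what}: unknown key(s) {unknown}; allowed: {sorted(keys)}")
    kwargs = {}
    for key, value in mapping.items():
        attr = keys[key]
        kwargs[attr] = str(value) if attr == "name" else float(value)  # type: ignore[arg-type]
    try:
        return cls(**kwargs)
    except TypeError as exc:  # missing required field
        raise ConfigError(f"{what}: {exc}") from None


def fluid_from_mapping(mapping: Mapping[str, object]) -> FluidProperties:
    """Build a fluid from a symbol-keyed mapping (rho0, c, beta, mu, ...).

    Unknown keys are rejected so that typos in configs fail loudly.
    """
    return _from_mapping(mapping, _FLUID_KEYS, FluidProperties, "fluid")


def particle_from_mapping(mapping: Mapping[str, object]) -> ParticleProperties:
    """Build a particle from a symbol-keyed mapping (rho0, beta, G, a, ...)."""
    return _from_mapping(mapping, _PARTICLE_KEYS, ParticleProperties, "particle")


def _to_mapping(obj, keys: Mapping[str, str]) -> dict[str, object]:
    out: dict[str, object] = {}
    for key, attr in keys.items():
        value = getattr(obj, attr)
        if value is None or (attr == "name" and not value):
            continue
        out[key] = value
    return out


def fluid_to_mapping(fluid: FluidProperties) -> dict[str, object]:
    return _to_mapping(fluid, _FLUID_KEYS)


def particle_to_mapping(particle: ParticleProperties) -> dict[str, object]:
    return _to_mapping(particle, _PARTICLE_KEYS)


def load_fluid(path: str | Path) -> FluidProperties:
    with open(path) as fh:
        return fluid_from_mapping(yaml.safe_load(fh))


def load_particle(path: str | Path) -> ParticleProperties:
    with open(path) as fh:
        return particle_from_mapping(yaml.safe_load(fh))


def save_materials(path: str | Path, *, fluid: FluidProperties | None = None,
                   particle: ParticleProperties | None = None) -> None:
    """Write fluid and/or particle mappings to a YAML file."""
    doc: dict[str, object] = {}
    if fluid is not None:
        doc["fluid"] = fluid_to_mapping(fluid)
    if particle is not None:
        doc["particle"] = particle_to_mapping(particle)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
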