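"""Standing plane-wave fields and their time-averaged first-order quantities.

A field is a superposition of standing plane-wave components at a common
frequency, all oscillating in phase in time (single ``cos(omega t)`` factor):

    p1(r, t) = A(r) cos(omega t),   A(r) = sum_j p_j cos(k r.e_j - phi_j)

with the coordinate origin at a pressure antinode of each component (cosine
convention).  The first-order velocity follows from the linearised momentum
balance rho df(v)/dt = -grad p1, so

    v1(r, t) = -grad A(r) sin(omega t) / (rho omega)

and the period averages used by the radiation-force model are closed forms:

    <p1^2> = A^2 / 2
    <v1^2> = |grad A|^2 / (2 rho^2 omega^2)

For the single-axis field A = p_ac cos(ky) these reduce to the familiar
p_ac^2 cos^2(ky)/2 and (p_ac/(rho c))^2 sin^2(ky)/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError
from .materials import FluidProperties, WATER

__all__ = [
    "WaveComponent",
    "StandingWaveSpec",
    "FieldSample",
    "acoustic_energy_density",
]


def acoustic_energy_density(peak_pressure: float, compressibility: float) -> float:
    """Acoustic energy density ``E_ac = beta_f p_ac^2 / 4`` (J m^-3).

    This is the energy scale of a single standing-wave component; the 1D
    closed-form force is linear in it.
    """
    if peak_pressure < 0.0 or not math.isfinite(peak_pressure):
        raise DomainError(f"peak pressure must be non-negative, got {peak_pressure!r}")
    if not (compressibility > 0.0):
        raise DomainError(f"compressibility must be positive, got {compressibility!r}")
    return compressibility * peak_pressure**2 / 4.0


@dataclass(frozen=True)
class WaveComponent:
    """One standing plane-wave component: unit axis, peak pressure, phase."""

    axis: tuple[float, ...]
    peak_pressure: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        if axis.ndim != 1 or axis.size not in (1, 2, 3):
            raise DomainError("axis must be a 1-, 2- or 3-vector")
        norm = float(np.linalg.norm(axis))
        if norm == 0.0:
            raise DomainError("axis must be non-zero")
        object.__setattr__(self, "axis", tuple(axis / norm))
        if self.peak_pressure < 0.0:
            raise DomainError(f"peak pressure must be non-negative, got {self.peak_pressure!r}")


@dataclass(frozen=True)
class FieldSample:
    """Field quantities at one position: <p_in^2> and <v_in^2>."""

    position: tuple[float, ...]
    mean_square_pressure: float
    mean_square_velocity: float

    def __post_init__(self) -> None:
        if self.mean_square_pressure < 0.0 or self.mean_square_velocity < 0.0:
            raise DomainError("mean-square field quantities must be non-negative")


@dataclass(frozen=True)
class StandingWaveSpec:
    """Standing acoustic field: components at a common wavelength in a fluid.

    ``ndim`` is set by the component axes (all must agree).  The wavenumber
    is ``k = 2 pi / lambda`` and the angular frequency ``omega = k c_f``.
    """

    components: tuple[WaveComponent, ...]
    wavelength: float
    fluid: FluidProperties = field(default=WATER)

    def __post_init__(self) -> None:
        if not (self.wavelength > 0.0):
            raise DomainError(f"wavelength must be positive, got {self.wavelength!r}")
        comps = tuple(self.components)
        if not comps:
            raise DomainError("at least one wave component is required")
        dims = {len(c.axis) for c in comps}
        if len(dims) != 1:
            raise DomainError(f"component axes have mixed dimensionality: {sorted(dims)}")
        object.__setattr__(self, "components", comps)

    # -- constructors -----------------------------------------------------

    @classmethod
    def one_dimensional(
        cls,
        wavelength: float,
        peak_pressure: float,
        fluid: FluidProperties = WATER,
        axis: tuple[float, ...] = (0.0, 1.0),
        phase: float = 0.0,
    ) -> "StandingWaveSpec":
        """Single standing wave ``p = p_ac cos(k r.e)``; default axis is +y."""
        return cls((WaveComponent(axis, peak_pressure, phase),), wavelength, fluid)

    @classmethod
    def perpendicular(
        cls,
        wavelength: float,
        peak_pressure: float,
        fluid: FluidProperties = WATER,
        phases: tuple[float, float] = (0.0, 0.0),
    ) -> "StandingWaveSpec":
        """Two equal-amplitude perpendicular components along x and y,
        mutually in phase by default (checkerboard node/antinode lattice)."""
        return cls(
            (
                WaveComponent((1.0, 0.0), peak_pressure, phases[0]),
                WaveComponent((0.0, 1.0), peak_pressure, phases[1]),
            ),
            wavelength,
            fluid,
        )

    # -- derived scalars --------------------------------------------------

    @property
    def ndim(self) -> int:
        return len(self.components[0].axis)

    @property
    def wavenumber(self) -> float:
        return 2.0 * math.pi / self.wavelength

    @property
    def angular_frequency(self) -> float:
        return self.wavenumber * self.fluid.sound_speed

    @property
    def frequency(self) -> float:
        return self.fluid.sound_speed / self.wavelength

    # -- spatial amplitude and derivatives --------------------------------

    def _phases_at(self, r: np.ndarray) -> np.ndarray:
        """Per-component spatial phases ``k r.e_j - phi_j``; shape (..., n_comp)."""
        r = np.asarray(r, dtype=float)
        axes = np.array([c.axis for c in self.components])          # (n, d)
        proj = r @ axes.T                                           # (..., n)
        phi = np.array([c.phase for c in self.components])
        return self.wavenumber * proj - phi

    def amplitude(self, r: np.ndarray) -> np.ndarray:
        """Spatial pressure amplitude ``A(r)``; shape ``r.shape[:-1]``."""
        amp = np.array([c.peak_pressure for c in self.components])
        return np.cos(self._phases_at(r)) @ amp

    def amplitude_gradient(self, r: np.ndarray) -> np.ndarray:
        """``grad A``; shape ``r.shape`` (last axis is the spatial dimension)."""
        amp = np.array([c.peak_pressure for c in self.components])
        axes = np.array([c.axis for c in self.components])
        return (-np.sin(self._phases_at(r)) * amp * self.wavenumber) @ axes

    def amplitude_hessian(self, r: np.ndarray) -> np.ndarray:
        """Hessian of ``A``; shape ``r.shape + (ndim,)``."""
        amp = np.array([c.peak_pressure for c in self.components])
        axes = np.array([c.axis for c in self.components])          # (n, d)
        outer = axes[:, :, None] * axes[:, None, :]                 # (n, d, d)
        coeff = -np.cos(self._phases_at(r)) * amp * self.wavenumber**2   # (..., n)
        return np.tensordot(coeff, outer, axes=([-1], [0]))

    # -- physical fields --------------------------------------------------

    def instantaneous_pressure(self, r: np.ndarray, t: float) -> np.ndarray:
        """First-order pressure ``A(r) cos(omega t)``."""
        if t < 0.0:
            raise DomainError(f"time must be non-negative, got {t!r}")
        return self.amplitude(r) * math.cos(self.angular_frequency * t)

    def instantaneous_velocity(self, r: np.ndarray, t: float) -> np.ndarray:
        """First-order fluid velocity ``-grad A sin(omega t) / (rho omega)``."""
        if t < 0.0:
            raise DomainError(f"time must be non-negative, got {t!r}")
        omega = self.angular_frequency
        return (
            -self.amplitude_gradient(r)
            * math.sin(omega * t)
            / (self.fluid.density * omega)
        )

    def mean_square_pressure(self, r: np.ndarray) -> np.ndarray:
        """Period-averaged ``<p_in^2> = A^2 / 2``."""
        return self.amplitude(r) ** 2 / 2.0

    def mean_square_velocity(self, r: np.ndarray) -> np.ndarray:
        """Period-averaged ``<v_in^2> = |grad A|^2 / (2 rho^2 omega^2)``."""
        grad = self.amplitude_gradient(r)
        scale = self.fluid.density * self.angular_frequency
        return np.sum(grad * grad, axis=-1) / (2.0 * scale**2)

    def sample(self, r) -> FieldSample:
        r = np.asarray(r, dtype=float)
        if r.ndim != 1:
            raise DomainError("sample() takes a single position vector")
        return FieldSample(
            position=tuple(r),
            mean_square_pressure=float(self.mean_square_pressure(r)),
            mean_square_velocity=float(self.mean_square_velocity(r)),
        )
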