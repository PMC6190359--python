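"""Acoustophoretic particle tracing in microchannel flow.

Particles are traced quasi-statically: at micron scales and sub-mm/s speeds
the Stokes response time (rho_p a^2 / mu ~ microseconds) is negligible, so
the particle velocity is the local fluid velocity plus the terminal drift
under the radiation force,

    dr/dt = u_flow(r) + F_ARF(r) / (6 pi mu a).

This is the standard closure for acoustophoresis at Reynolds numbers well
below one.  Gravity/buoyancy and particle-particle interactions are
neglected; finite particle size enters only through the force model (the
volume-averaged force) and the drag radius.

The module covers the two canonical device scenarios: continuous-flow
separation (trace through a channel, classify by outlet) and patterning
(locate the stable equilibria of the force field, i.e. the node lattice
for positive-contrast particles).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DomainError
from .fields import StandingWaveSpec
from .materials import FluidProperties, ParticleProperties
from .radforce import (
    ModelName,
    ScatteringCoefficients,
    finite_size_force,
    modifying_factor,
    small_particle_force,
)

__all__ = [
    "ChannelSpec",
    "Trajectory",
    "SeparationReport",
    "drag_mobility",
    "force_function",
    "advance_trajectory",
    "simulate_separation",
    "find_equilibria",
]


def drag_mobility(a: float, viscosity: float) -> float:
    """Stokes-drag mobility ``1 / (6 pi mu a)`` (m s^-1 N^-1)."""
    if not (a > 0.0 and viscosity > 0.0):
        raise DomainError("radius and viscosity must be positive")
    return 1.0 / (6.0 * math.pi * viscosity * a)


@dataclass(frozen=True)
class ChannelSpec:
    """Straight microchannel: axial flow along +x, lateral coordinate y in [0, width].

    ``center_band`` are the lateral cut positions separating the centre
    outlet from the side outlets; particles ending inside the band leave
    through the centre outlet (un-captured sample stream), outside it
    through a side outlet (sheath stream).
    """

    width: float
    length: float
    mean_speed: float
    profile: Literal["plug", "parabolic"] = "plug"
    center_band: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.width > 0.0 and self.length > 0.0 and self.mean_speed > 0.0):
            raise DomainError("width, length and mean speed must be positive")
        if self.profile not in ("plug", "parabolic"):
            raise DomainError(f"unknown flow profile {self.profile!r}")
        lo, hi = self.center_band
        if (lo, hi) != (0.0, 0.0) and not (0.0 < lo < hi < self.width):
            raise DomainError(
                f"center_band cut positions must satisfy 0 < lo < hi < width, got {self.center_band!r}"
            )

    def axial_speed(self, y: np.ndarray) -> np.ndarray:
        """Axial flow speed at lateral position(s) ``y``."""
        y = np.asarray(y, dtype=float)
        if self.profile == "plug":
            return np.full_like(y, self.mean_speed)
        # Poiseuille between parallel walls at y = 0 and y = width
        return 6.0 * self.mean_speed * y * (self.width - y) / self.width**2

    def flow_velocity(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        out = np.zeros_like(r)
        out[..., 0] = self.axial_speed(r[..., 1])
        return out

    @property
    def transit_time(self) -> float:
        """Nominal residence time ``length / mean_speed``."""
        return self.length / self.mean_speed

    def classify_outlet(self, y: float) -> str:
        lo, hi = self.center_band
        return "center" if lo <= y <= hi else "side"


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped particle path through the device."""

    times: np.ndarray
    positions: np.ndarray
    model: str
    particle_id: int = 0
    exited: bool = False

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        positions = np.asarray(self.positions, dtype=float)
        if np.any(np.diff(times) <= 0.0):
            raise DomainError("trajectory times must be strictly increasing")
        if not np.all(np.isfinite(positions)):
            raise DomainError("trajectory positions must be finite")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", positions)

    @property
    def final_position(self) -> np.ndarray:
        return self.positions[-1]

    def to_dataframe(self):
        import pandas as pd

        ndim = self.positions.shape[1]
        cols = {"particle_id": self.particle_id, "t_s": self.times}
        for i, name in enumerate("xyz"[:ndim]):
            cols[f"{name}_m"] = self.positions[:, i]
        cols["model"] = self.model
        return pd.DataFrame(cols)

    def save_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class SeparationReport:
    """Outlet assignment per released particle, plus counts."""

    assignments: tuple[str, ...]
    model: str
    trajectories: tuple[Trajectory, ...] = ()

    @property
    def counts(self) -> dict[str, int]:
        return {
            outlet: sum(1 for o in self.assignments if o == outlet)
            for outlet in ("center", "side")
        }

    @property
    def total(self) -> int:
        return len(self.assignments)

    def summary_text(self) -> str:
        lines = [f"model: {self.model}", f"particles: {self.total}"]
        for outlet, count in self.counts.items():
            lines.append(f"{outlet}: {count}")
        return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# force closures
# --------------------------------------------------------------------------

def force_function(
    spec: StandingWaveSpec,
    coeffs: ScatteringCoefficients,
    a: float,
    model: ModelName,
    force_scale: float = 1.0,
    quad_rtol: float = 1.0e-6,
) -> Callable[[np.ndarray], np.ndarray]:
    """Return ``r -> F_ARF(r)`` for the chosen force model.

    For a single-component field the volume average is exactly the
    point-scatterer force times ``f_m(ka)``, so the finite-size closure
    stays closed-form there; multi-component fields fall back to the
    sphere/disk quadrature at every evaluation.
    """
    volume = 4.0 / 3.0 * math.pi * a**3
    if model == "small_particle":
        def force(r: np.ndarray) -> np.ndarray:
            return force_scale * small_particle_force(spec, r, coeffs, volume)
        return force
    if model != "finite_size":
        raise DomainError(f"unknown force model {model!r}")
    if len(spec.components) == 1:
        fm = float(modifying_factor(spec.wavenumber * a))
        def force(r: np.ndarray) -> np.ndarray:
            return force_scale * fm * small_particle_force(spec, r, coeffs, volume)
        return force
    dim = 2 if spec.ndim == 2 else 3
    def force(r: np.ndarray) -> np.ndarray:
        return force_scale * finite_size_force(
            spec, np.asarray(r, float), a, coeffs, dim=dim, rtol=quad_rtol
        )
    return force


def _embed_field_position(r: np.ndarray, spec: StandingWaveSpec) -> np.ndarray:
    """Map a channel position (x axial, y lateral) to field coordinates.

    1D field specs live on the lateral coordinate only; 2D specs use the
    channel plane directly.
    """
    if spec.ndim == 2:
        return r
    if spec.ndim == 1:
        return r[..., 1:2]
    raise DomainError("tracing supports 1D or 2D field specs")


# --------------------------------------------------------------------------
# integration
# --------------------------------------------------------------------------

def advance_trajectory(
    channel: ChannelSpec,
    spec: StandingWaveSpec,
    particle: ParticleProperties,
    coeffs: ScatteringCoefficients,
    model: ModelName,
    r0: Sequence[float],
    duration: float,
    viscosity: float | None = None,
    force_scale: float = 1.0,
    rtol: float = 1.0e-8,
    atol: float | None = None,
    fixed_dt: float | None = None,
    n_samples: int = 201,
    particle_id: int = 0,
) -> Trajectory:
    """Integrate ``dr/dt = u_flow + mobility * F_ARF`` from ``r0`` for ``duration``.

    The default integrator is adaptive RK45; passing ``fixed_dt`` switches
    to a fixed-step classical RK4 scheme whose output is bit-reproducible
    across runs (for regression pinning).  If the particle leaves the
    channel (axially or laterally) the trajectory is truncated at the exit
    and flagged, which is an outcome, not an error.
    """
    r0 = np.asarray(r0, dtype=float)
    if not (0.0 <= r0[0] <= channel.length and 0.0 <= r0[1] <= channel.width):
        raise DomainError(f"release position {r0!r} outside channel")
    if not (duration > 0.0):
        raise DomainError("duration must be positive")
    mu = viscosity if viscosity is not None else spec.fluid.shear_viscosity
    if mu is None:
        raise DomainError("fluid has no shear viscosity; pass viscosity explicitly")
    mobility = drag_mobility(particle.radius, mu)
    force = force_function(spec, coeffs, particle.radius, model, force_scale=force_scale)

    def rhs(t: float, r: np.ndarray) -> np.ndarray:
        drift = np.zeros_like(r)
        f = force(_embed_field_position(r, spec))
        if spec.ndim == 1:
            drift[1] = mobility * f[0]
        else:
            drift[:2] += mobility * f
        return channel.flow_velocity(r) + drift

    times = np.linspace(0.0, duration, n_samples)
    if fixed_dt is not None:
        ts, ys = _rk4(rhs, r0, duration, fixed_dt)
    else:
        if atol is None:
            atol = 1.0e-6 * spec.wavelength
        sol = solve_ivp(
            rhs, (0.0, duration), r0, method="RK45", t_eval=times, rtol=rtol, atol=atol,
            max_step=duration / 20.0,
        )
        ts, ys = sol.t, sol.y.T
    inside = (
        (ys[:, 0] <= channel.length)
        & (ys[:, 1] >= 0.0)
        & (ys[:, 1] <= channel.width)
    )
    exited = bool(np.any(~inside))
    if exited:
        last = int(np.argmax(~inside))  # first sample outside; keep it as the exit point
        ts, ys = ts[: last + 1], ys[: last + 1]
    return Trajectory(
        times=ts, positions=ys, model=model, particle_id=particle_id, exited=exited
    )


def _rk4(rhs, r0: np.ndarray, duration: float, dt: float):
    n = max(1, int(math.ceil(duration / dt)))
    dt = duration / n
    ts = np.empty(n + 1)
    ys = np.empty((n + 1, r0.size))
    ts[0], ys[0] = 0.0, r0
    r = r0.astype(float)
    for i in range(n):
        t = i * dt
        k1 = rhs(t, r)
        k2 = rhs(t + dt / 2.0, r + dt / 2.0 * k1)
        k3 = rhs(t + dt / 2.0, r + dt / 2.0 * k2)
        k4 = rhs(t + dt, r + dt * k3)
        r = r + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        ts[i + 1], ys[i + 1] = (i + 1) * dt, r
    return ts, ys


def simulate_separation(
    channel: ChannelSpec,
    spec: StandingWaveSpec,
    particle: ParticleProperties,
    coeffs: ScatteringCoefficients,
    model: ModelName,
    release_positions: Sequence[float],
    force_scale: float = 1.0,
    fixed_dt: float | None = None,
    keep_trajectories: bool = True,
) -> SeparationReport:
    """Trace particles released at the inlet and classify their outlets.

    ``release_positions`` are lateral (y) positions at the channel inlet.
    Each particle is traced for the channel transit time; its final lateral
    position decides the outlet (centre band vs side).  Because the
    finite-size force is the small-particle force scaled by f_m <= 1 in a
    one-directional field, the finite-size model never captures more
    particles to the side outlets than the small-particle model.
    """
    if len(release_positions) == 0:
        raise DomainError("at least one release position is required")
    duration = channel.transit_time
    assignments: list[str] = []
    trajectories: list[Trajectory] = []
    for pid, y0 in enumerate(release_positions):
        traj = advance_trajectory(
            channel, spec, particle, coeffs, model, (0.0, float(y0)), duration,
            force_scale=force_scale, fixed_dt=fixed_dt, particle_id=pid,
        )
        assignments.append(channel.classify_outlet(float(traj.final_position[1])))
        if keep_trajectories:
            trajectories.append(traj)
    return SeparationReport(
        assignments=tuple(assignments), model=model, trajectories=tuple(trajectories)
    )


# --------------------------------------------------------------------------
# equilibria / patterning
# --------------------------------------------------------------------------

def find_equilibria(
    spec: StandingWaveSpec,
    particle: ParticleProperties,
    coeffs: ScatteringCoefficients,
    model: ModelName,
    bbox: Sequence[tuple[float, float]],
    seeds_per_axis: int = 6,
    viscosity: float | None = None,
    position_tol: float | None = None,
    max_time_constants: float = 400.0,
) -> np.ndarray:
    """Locate stable rest positions of the radiation force within ``bbox``.

    Seeds a grid of particles and relaxes each along the overdamped
    dynamics ``dr/dt = mobility F(r)`` until the drift stalls, then keeps
    the distinct converged points whose force Jacobian is stable (all
    eigenvalue real parts negative).  For positive acoustic contrast these
    are the pressure-node lattice; for negative contrast, the antinodes.
    Seeds that fail to settle within the iteration budget are dropped.
    """
    bbox = [tuple(map(float, ax)) for ax in bbox]
    if len(bbox) != spec.ndim:
        raise DomainError(f"bbox must have {spec.ndim} axis ranges")
    for lo, hi in bbox:
        if not (hi - lo >= spec.wavelength):
            raise DomainError("bbox must span at least one wavelength per axis")
    if position_tol is None:
        position_tol = 1.0e-4 * spec.wavelength
    mu = viscosity if viscosity is not None else spec.fluid.shear_viscosity
    if mu is None:
        raise DomainError("fluid has no shear viscosity; pass viscosity explicitly")
    mobility = drag_mobility(particle.radius, mu)
    force = force_function(spec, coeffs, particle.radius, model)

    # relaxation time scale from the 1D stiffness 8 pi |Phi| a^3 k^2 E_ac
    from .fields import acoustic_energy_density

    p_ref = max(c.peak_pressure for c in spec.components)
    e_ac = acoustic_energy_density(p_ref, spec.fluid.compressibility)
    stiffness = (
        8.0 * math.pi * abs(coeffs.contrast_factor) * particle.radius**3
        * spec.wavenumber**2 * e_ac
    )
    if stiffness == 0.0:
        raise DomainError("zero acoustic contrast: no equilibria to find")
    tau = 1.0 / (mobility * stiffness)

    grids = [np.linspace(lo, hi, seeds_per_axis + 2)[1:-1] for lo, hi in bbox]
    mesh = np.meshgrid(*grids, indexing="ij")
    seeds = np.stack([m.ravel() for m in mesh], axis=-1)

    def rhs(t, r):
        return mobility * force(r)

    found: list[np.ndarray] = []
    f_tol = 1.0e-8 * stiffness * spec.wavelength  # force at position_tol-scale offsets
    for seed in seeds:
        sol = solve_ivp(
            rhs, (0.0, max_time_constants * tau), seed, method="RK45",
            rtol=1.0e-8, atol=1.0e-8 * spec.wavelength,
        )
        r_end = sol.y[:, -1]
        if float(np.linalg.norm(force(r_end))) > f_tol:
            continue  # flagged: did not settle within budget
        if not _is_stable(force, r_end, 1.0e-4 * spec.wavelength):
            continue
        if any(np.linalg.norm(r_end - p) < 10.0 * position_tol for p in found):
            continue
        if all(lo - position_tol <= x <= hi + position_tol for x, (lo, hi) in zip(r_end, bbox)):
            found.append(r_end)
    return np.array(sorted(found, key=tuple)) if found else np.empty((0, spec.ndim))


def _is_stable(force: Callable[[np.ndarray], np.ndarray], r: np.ndarray, h: float) -> bool:
    ndim = r.size
    jac = np.empty((ndim, ndim))
    for j in range(ndim):
        dr = np.zeros(ndim)
        dr[j] = h
        jac[:, j] = (force(r + dr) - force(r - dr)) / (2.0 * h)
    return bool(np.all(np.real(np.linalg.eigvals(jac)) < 0.0))
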