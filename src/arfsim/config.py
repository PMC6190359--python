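"""Scenario configuration: YAML/JSON schema, validation and object builders.

A scenario file has four blocks::

    schema_version: 1
    materials:            # registry names or symbol-keyed mappings
      fluid: water
      particle: nih3t3
      particle_radius_m: 5.0e-6        # optional override
    field:
      wavelength_m: 6.0e-5
      components:
        - axis: [0.0, 1.0]
          peak_pressure_pa: 2.0e5
          phase_rad: 0.0
    run:
      kind: force_curve | force_map | trace | separate
      ...                              # kind-specific keys, see _RUN_KEYS

All physical quantities are SI and the unit is part of the key name
(``…_m``, ``…_pa``, ``…_s``).  Validation errors carry the dotted path of
the offending field.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError
from .fields import StandingWaveSpec, WaveComponent
from .materials import (
    NIH3T3,
    WATER,
    FluidProperties,
    ParticleProperties,
    fluid_from_mapping,
    particle_from_mapping,
)
from .tracing import ChannelSpec

SCHEMA_VERSION = 1

__all__ = [
    "SCHEMA_VERSION",
    "load_config",
    "validate_config",
    "config_sha256",
    "build_fluid",
    "build_particle",
    "build_field",
    "build_channel",
]

_FLUID_REGISTRY = {"water": WATER}
_PARTICLE_REGISTRY = {"nih3t3": NIH3T3}

_RUN_KEYS: Mapping[str, set[str]] = {
    "force_curve": {"kind", "ratios", "node_offset_m", "quad_rtol"},
    "force_map": {"kind", "bbox_m", "resolution", "models", "dp_over_lambda", "quad_rtol"},
    "trace": {"kind", "channel", "model", "release_m", "duration_s", "fixed_dt_s",
              "force_scale"},
    "separate": {"kind", "channel", "models", "release_positions_m", "fixed_dt_s",
                 "force_scale"},
}

_CHANNEL_KEYS = {"width_m", "length_m", "mean_speed_m_s", "profile", "center_band_m"}


def _err(path: str, message: str) -> ConfigError:
    return ConfigError(f"{path}: {message}")


def _require(doc: Mapping[str, Any], path: str, key: str) -> Any:
    if key not in doc:
        raise _err(f"{path}.{key}" if path else key, "missing required key")
    return doc[key]


def _positive(value: Any, path: str) -> float:
    try:
        value = float(value)
    except (TypeError, ValueError):
        raise _err(path, f"expected a number, got {value!r}") from None
    if not value > 0.0:
        raise _err(path, f"must be strictly positive, got {value!r}")
    return value


def load_config(path: str | Path) -> dict[str, Any]:
    """Load and validate a scenario config (YAML; JSON is valid YAML)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    validate_config(doc)
    return doc


def config_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def validate_config(doc: Any) -> None:
    """Validate a scenario document against the schema; raise ConfigError."""
    if not isinstance(doc, Mapping):
        raise ConfigError("config root must be a mapping")
    version = _require(doc, "", "schema_version")
    if version != SCHEMA_VERSION:
        raise _err("schema_version", f"expected {SCHEMA_VERSION}, got {version!r}")
    unknown = set(doc) - {"schema_version", "materials", "field", "run", "output"}
    if unknown:
        raise _err(sorted(unknown)[0], "unknown top-level key")

    materials = _require(doc, "", "materials")
    if not isinstance(materials, Mapping):
        raise _err("materials", "must be a mapping")
    bad = set(materials) - {"fluid", "particle", "particle_radius_m"}
    if bad:
        raise _err(f"materials.{sorted(bad)[0]}", "unknown key")
    fluid = _require(materials, "materials", "fluid")
    if isinstance(fluid, str):
        if fluid not in _FLUID_REGISTRY:
            raise _err("materials.fluid", f"unknown fluid {fluid!r}; built-ins: "
                       f"{sorted(_FLUID_REGISTRY)}")
    elif not isinstance(fluid, Mapping):
        raise _err("materials.fluid", "must be a registry name or a mapping")
    particle = _require(materials, "materials", "particle")
    if isinstance(particle, str):
        if particle not in _PARTICLE_REGISTRY:
            raise _err("materials.particle", f"unknown particle {particle!r}; built-ins: "
                       f"{sorted(_PARTICLE_REGISTRY)}")
    elif not isinstance(particle, Mapping):
        raise _err("materials.particle", "must be a registry name or a mapping")
    if "particle_radius_m" in materials:
        _positive(materials["particle_radius_m"], "materials.particle_radius_m")

    field = _require(doc, "", "field")
    if not isinstance(field, Mapping):
        raise _err("field", "must be a mapping")
    bad = set(field) - {"wavelength_m", "components"}
    if bad:
        raise _err(f"field.{sorted(bad)[0]}", "unknown key")
    _positive(_require(field, "field", "wavelength_m"), "field.wavelength_m")
    components = _require(field, "field", "components")
    if not isinstance(components, list) or not components:
        raise _err("field.components", "must be a non-empty list")
    for i, comp in enumerate(components):
        cpath = f"field.components[{i}]"
        if not isinstance(comp, Mapping):
            raise _err(cpath, "must be a mapping")
        bad = set(comp) - {"axis", "peak_pressure_pa", "phase_rad"}
        if bad:
            raise _err(f"{cpath}.{sorted(bad)[0]}", "unknown key")
        axis = _require(comp, cpath, "axis")
        if not isinstance(axis, list) or len(axis) not in (1, 2, 3):
            raise _err(f"{cpath}.axis", "must be a 1-, 2- or 3-element list")
        if all(float(x) == 0.0 for x in axis):
            raise _err(f"{cpath}.axis", "must be non-zero")
        _positive(_require(comp, cpath, "peak_pressure_pa"), f"{cpath}.peak_pressure_pa")

    run = _require(doc, "", "run")
    if not isinstance(run, Mapping):
        raise _err("run", "must be a mapping")
    kind = _require(run, "run", "kind")
    if kind not in _RUN_KEYS:
        raise _err("run.kind", f"must be one of {sorted(_RUN_KEYS)}, got {kind!r}")
    bad = set(run) - _RUN_KEYS[kind]
    if bad:
        raise _err(f"run.{sorted(bad)[0]}", f"unknown key for kind {kind!r}")
    _validate_run(run, kind)


def _validate_run(run: Mapping[str, Any], kind: str) -> None:
    if kind == "force_curve":
        ratios = run.get("ratios")
        if ratios is not None:
            if isinstance(ratios, Mapping):
                for key in ("start", "stop", "num"):
                    if key not in ratios:
                        raise _err(f"run.ratios.{key}", "missing required key")
            elif not isinstance(ratios, list):
                raise _err("run.ratios", "must be a list or {start, stop, num}")
    elif kind == "force_map":
        bbox = _require(run, "run", "bbox_m")
        if (
            not isinstance(bbox, list) or len(bbox) != 2
            or any(not isinstance(ax, list) or len(ax) != 2 for ax in bbox)
        ):
            raise _err("run.bbox_m", "must be [[x0, x1], [y0, y1]]")
        for ax_i, (lo, hi) in enumerate(bbox):
            if not float(hi) > float(lo):
                raise _err(f"run.bbox_m[{ax_i}]", "degenerate range")
        res = _require(run, "run", "resolution")
        if not isinstance(res, int) or res < 2:
            raise _err("run.resolution", f"must be an integer >= 2, got {res!r}")
    elif kind in ("trace", "separate"):
        channel = _require(run, "run", "channel")
        if not isinstance(channel, Mapping):
            raise _err("run.channel", "must be a mapping")
        bad = set(channel) - _CHANNEL_KEYS
        if bad:
            raise _err(f"run.channel.{sorted(bad)[0]}", "unknown key")
        for key in ("width_m", "length_m", "mean_speed_m_s"):
            _positive(_require(channel, "run.channel", key), f"run.channel.{key}")
        band = channel.get("center_band_m")
        if band is not None:
            if not isinstance(band, list) or len(band) != 2:
                raise _err("run.channel.center_band_m", "must be [lo, hi]")
            lo, hi = map(float, band)
            width = float(channel["width_m"])
            if not (0.0 < lo < hi < width):
                raise _err("run.channel.center_band_m",
                           f"cuts must satisfy 0 < lo < hi < width ({width})")
        if kind == "trace":
            release = _require(run, "run", "release_m")
            if not isinstance(release, list) or len(release) != 2:
                raise _err("run.release_m", "must be [x, y]")
            _positive(_require(run, "run", "duration_s"), "run.duration_s")
        else:
            releases = _require(run, "run", "release_positions_m")
            if not isinstance(releases, list) or not releases:
                raise _err("run.release_positions_m", "must be a non-empty list")
    if "models" in run:
        models = run["models"]
        if not isinstance(models, list) or not models:
            raise _err("run.models", "must be a non-empty list")
        for m in models:
            if m not in ("small_particle", "finite_size"):
                raise _err("run.models", f"unknown model {m!r}")
    if "model" in run and run["model"] not in ("small_particle", "finite_size"):
        raise _err("run.model", f"unknown model {run['model']!r}")


# --------------------------------------------------------------------------
# builders
# --------------------------------------------------------------------------

def build_fluid(doc: Mapping[str, Any]) -> FluidProperties:
    fluid = doc["materials"]["fluid"]
    if isinstance(fluid, str):
        return _FLUID_REGISTRY[fluid]
    return fluid_from_mapping(fluid)


def build_particle(doc: Mapping[str, Any]) -> ParticleProperties:
    particle = doc["materials"]["particle"]
    obj = _PARTICLE_REGISTRY[particle] if isinstance(particle, str) else (
        particle_from_mapping(particle)
    )
    radius = doc["materials"].get("particle_radius_m")
    if radius is not None:
        obj = obj.with_radius(float(radius))
    return obj


def build_field(doc: Mapping[str, Any]) -> StandingWaveSpec:
    field = doc["field"]
    components = tuple(
        WaveComponent(
            axis=tuple(float(x) for x in comp["axis"]),
            peak_pressure=float(comp["peak_pressure_pa"]),
            phase=float(comp.get("phase_rad", 0.0)),
        )
        for comp in field["components"]
    )
    return StandingWaveSpec(
        components=components,
        wavelength=float(field["wavelength_m"]),
        fluid=build_fluid(doc),
    )


def build_channel(doc: Mapping[str, Any]) -> ChannelSpec:
    channel = doc["run"]["channel"]
    band = channel.get("center_band_m")
    return ChannelSpec(
        width=float(channel["width_m"]),
        length=float(channel["length_m"]),
        mean_speed=float(channel["mean_speed_m_s"]),
        profile=channel.get("profile", "plug"),
        center_band=(float(band[0]), float(band[1])) if band else (0.0, 0.0),
    )


def run_parameters(doc: Mapping[str, Any]) -> dict[str, Any]:
    """Flatten the physical parameters actually in effect, for run logs."""
    fluid = build_fluid(doc)
    particle = build_particle(doc)
    field = doc["field"]
    return {
        "schema_version": doc["schema_version"],
        "fluid": {"rho0": fluid.density, "c": fluid.sound_speed,
                  "beta": fluid.compressibility},
        "particle": {"rho0": particle.density, "beta": particle.compressibility,
                     "G": particle.shear_modulus, "a": particle.radius},
        "wavelength_m": float(field["wavelength_m"]),
        "peak_pressures_pa": [float(c["peak_pressure_pa"]) for c in field["components"]],
        "run_kind": doc["run"]["kind"],
    }


def dump_json(obj: Any, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
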