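"""Run configuration: a validated, serializable description of a full
simulation (geometry, fluid, particle, chemistry, fields, run sizes).

Configurations load from YAML; unknown keys are rejected and out-of-range
values name the offending key.  ``RunConfig.to_dict`` / ``from_dict`` round-
trip exactly, which is what the provenance hashes rely on.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import constants as c


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass
class RunConfig:
    """Top-level run description (SI units).

    ``geometry`` holds :class:`~nanodiff.geometry.GeometrySpec` fields, or
    ``{"file": path}`` to load a pre-generated lattice; the remaining groups
    mirror the physical property sets.
    """

    geometry: dict = field(default_factory=lambda: {"domain_kind": "ecm", "target_porosity": 0.95})
    viscosity: float = c.WATER_VISCOSITY
    temperature: float = c.BODY_TEMPERATURE
    particle: dict = field(default_factory=dict)  # NanoparticleProps fields
    chemistry: dict | None = None  # SurfaceChemistry fields; None -> no wall forces
    fields: dict = field(default_factory=dict)  # FieldConfig fields
    n_particles: int = 120
    replicates: int = 50
    n_steps: int = 2000
    sample_every: int = 5
    dt: float | None = None
    brownian_mode: str = "fixed"
    stick_probability: float | None = None
    seed: int = 0
    output_dir: str = "."

    _POSITIVE = ("viscosity", "temperature", "n_particles", "replicates", "n_steps", "sample_every")

    def __post_init__(self) -> None:
        for key in self._POSITIVE:
            if not getattr(self, key) > 0:
                raise ConfigError(f"configuration key {key!r} must be positive")
        if self.dt is not None and self.dt <= 0:
            raise ConfigError("configuration key 'dt' must be positive")
        if self.brownian_mode not in ("fixed", "gaussian"):
            raise ConfigError("configuration key 'brownian_mode' must be 'fixed' or 'gaussian'")
        if not isinstance(self.seed, int):
            raise ConfigError("configuration key 'seed' must be an integer")
        known_particle = {f.name for f in _props_fields()}
        for k in self.particle:
            if k not in known_particle:
                raise ConfigError(f"unknown particle key {k!r}")
        if self.chemistry is not None:
            known_chem = {f.name for f in _chem_fields()}
            for k in self.chemistry:
                if k not in known_chem:
                    raise ConfigError(f"unknown chemistry key {k!r}")
        for k in ("diameter", "density"):
            if k in self.particle and not self.particle[k] > 0:
                raise ConfigError(f"configuration key 'particle.{k}' must be positive")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def build(self):
        """Materialize the physical objects this config describes:
        (lattice, TransportConfig)."""
        from .forces import FieldConfig, NanoparticleProps, SurfaceChemistry
        from .geometry import GeometrySpec, generate_ecm, generate_sphere_array, generate_tumor
        from .transport import TransportConfig

        geo = dict(self.geometry)
        if "file" in geo:
            from .io import load_geometry

            lattice, _ = load_geometry(geo["file"])
        else:
            spec = GeometrySpec(**geo)
            if spec.domain_kind == "ecm":
                lattice = generate_ecm(spec)
            elif spec.domain_kind == "tumor":
                lattice = generate_tumor(spec)
            else:
                raise ConfigError("sphere_array geometry requires explicit parameters; "
                                  "use geometry.generate_sphere_array directly")
        props = NanoparticleProps(**self.particle)
        chem = SurfaceChemistry(**self.chemistry) if self.chemistry is not None else None
        fieldcfg = FieldConfig(**self.fields)
        tcfg = TransportConfig(
            props=props, chem=chem, lattice=lattice, viscosity=self.viscosity,
            temperature=self.temperature, dt=self.dt, n_steps=self.n_steps,
            n_particles=self.n_particles, sample_every=self.sample_every,
            replicates=self.replicates, seed=self.seed,
            fieldcfg=fieldcfg, brownian_mode=self.brownian_mode,
            stick_probability=self.stick_probability,
        )
        return lattice, tcfg


def _props_fields():
    from .forces import NanoparticleProps

    return dataclasses.fields(NanoparticleProps)


def _chem_fields():
    from .forces import SurfaceChemistry

    return dataclasses.fields(SurfaceChemistry)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    return RunConfig.from_dict(raw)


def save_config(path, cfg: RunConfig) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
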