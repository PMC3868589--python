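"""Run configuration: YAML schema with all model defaults built in.

An empty config reproduces the reference experiment (50/73.6 ml geometry,
reference cycle anchors, printed material constants, coarse 12x6x7 mesh).
Every block is optional; unknown keys are rejected with field-level
diagnostics.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .fe import BoundaryConditions, SolverSettings
from .inverse import InverseSettings
from .materials import FiberConstituents, OgdenParams
from .waveforms import CycleSpec

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GeometryConfig:
    cavity_volume: float = 50.0       # ml
    wall_volume: float = 73.6         # ml
    aspect_ratio: float = 2.0         # a_endo / b_endo
    truncation_fraction: float = 2.0 / 3.0
    n_circ: int = 12                  # reference discretisation uses 48
    n_long: int = 6
    n_layers: int = 7
    calibrate: bool = True


@dataclass(frozen=True)
class MaterialConfig:
    ogden_mu: tuple = (220.0, 110.0)      # kPa
    ogden_alpha: tuple = (11.77, 14.34)
    collagen_E: float = 50.0              # kPa
    collagen_nu: float = 0.49
    collagen_rho: float = 1000.0
    vf_myo: float = 0.7
    vf_collagen: float = 0.015
    e_active_max: float = 500.0           # kPa (0.5 MPa cap)
    vol_form: str = "quadratic"
    active_fiber_law: str = "compression"
    collagen_fiber_law: str = "compression"


def _from_dict(cls, data, context):
    if data is None:
        return cls()
    if not isinstance(data, dict):
        raise ConfigError(f"{context}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}; valid: {sorted(names)}")
    kwargs = {}
    for f in fields(cls):
        if f.name in data:
            v = data[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{context}: {exc}") from exc


@dataclass(frozen=True)
class RunConfig:
    cycle: CycleSpec = field(default_factory=CycleSpec)
    cycle_csv: str | None = None          # overrides the synthetic cycle
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    materials: MaterialConfig = field(default_factory=MaterialConfig)
    solver: SolverSettings = field(default_factory=SolverSettings)
    bcs: BoundaryConditions = field(default_factory=BoundaryConditions)
    inverse: InverseSettings = field(default_factory=InverseSettings)
    output_dir: str = "results"
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict | None) -> "RunConfig":
        data = dict(data or {})
        known = {
            "cycle", "cycle_csv", "geometry", "materials", "solver",
            "bcs", "inverse", "output_dir", "seed",
        }
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"run config: unknown blocks {sorted(unknown)}")
        cfg = cls(
            cycle=_from_dict(CycleSpec, data.get("cycle"), "cycle"),
            cycle_csv=data.get("cycle_csv"),
            geometry=_from_dict(GeometryConfig, data.get("geometry"), "geometry"),
            materials=_from_dict(MaterialConfig, data.get("materials"), "materials"),
            solver=_from_dict(SolverSettings, data.get("solver"), "solver"),
            bcs=_from_dict(BoundaryConditions, data.get("bcs"), "bcs"),
            inverse=_from_dict(InverseSettings, data.get("inverse"), "inverse"),
            output_dir=data.get("output_dir", "results"),
            seed=int(data.get("seed", 0)),
        )
        cfg.cycle.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def ogden(self) -> OgdenParams:
        return OgdenParams(mu=tuple(self.materials.ogden_mu),
                           alpha=tuple(self.materials.ogden_alpha))

    def constituents(self) -> FiberConstituents:
        m = self.materials
        return FiberConstituents(
            vf_myo=m.vf_myo, vf_collagen=m.vf_collagen,
            collagen_E=m.collagen_E, collagen_nu=m.collagen_nu,
            collagen_rho=m.collagen_rho,
        )
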