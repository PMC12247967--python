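"""YAML run configuration with strict schema validation.

A single config file carries per-subcommand sections so that paired runs
(e.g. a sweep and a simulation, or a synthetic table and its statistics)
share one geometry description.  Unknown keys are rejected with the
offending key named; defaults are the model-parameter table of the study
(ellipsoid 10 × 6 µm, kgen = 0.01 µm⁻³ s⁻¹, dt = 1e-4 s, parameter
ranges kon 1e-3–1e-1 s⁻¹, Dv 0.01–0.5 µm² s⁻¹, beta 0.1–10 µm).
Every run writes a fully resolved copy of its configuration next to its
outputs so the artifact directory is self-describing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "resolve_and_write"]


@dataclass
class GeometrySection:
    major_axis: float = 10.0
    minor_axis: float = 6.0
    domain_lengths: tuple = (10.5, 6.6, 6.6)
    counts: tuple = (64, 40, 40)


@dataclass
class PlacementSection:
    preset: str = "adjacent2_distant1"
    adjacent_angle: float = 60.0
    beta: float = 3.0


@dataclass
class TransportSection:
    kgen: float = 0.01
    kon: float = 1e-2
    Dv: float = 0.1
    dt: float = 1e-4
    t_max: float = 1e4
    steady_tol: float = 1e-6


@dataclass
class SweepSection:
    kon_values: tuple = (1e-3, 1e-2, 1e-1)
    Dv_values: tuple = (0.01, 0.07, 0.5)
    beta_values: tuple = (0.1, 1.0, 3.0, 10.0)


@dataclass
class OracleSection:
    n_particles: int = 10_000
    step_dt: float = 0.01
    max_time: float = 5_000.0


@dataclass
class SynthSection:
    n_mothers: int = 200
    summed_fraction: float = 0.45
    cv_two_bud: float = 0.12
    cv_overall: float = 0.20
    fold_span: float = 70.0


@dataclass
class StatsSection:
    emergence_threshold: float = 1.0
    compensation_margin: float = 0.25
    window: int = 10


@dataclass
class RunConfig:
    geometry: GeometrySection = field(default_factory=GeometrySection)
    placement: PlacementSection = field(default_factory=PlacementSection)
    transport: TransportSection = field(default_factory=TransportSection)
    sweep: SweepSection = field(default_factory=SweepSection)
    oracle: OracleSection = field(default_factory=OracleSection)
    synth: SynthSection = field(default_factory=SynthSection)
    stats: StatsSection = field(default_factory=StatsSection)
    output_dir: str = "multibud_out"
    seed: int = 42
    log_level: str = "INFO"

    def validate(self) -> None:
        t = self.transport
        for name in ("kgen", "kon"):
            if getattr(t, name) < 0:
                raise ValueError(f"config key transport.{name} must be non-negative")
        for name in ("Dv", "dt", "t_max", "steady_tol"):
            if getattr(t, name) <= 0:
                raise ValueError(f"config key transport.{name} must be positive")
        g = self.geometry
        if g.major_axis <= 0 or g.minor_axis <= 0:
            raise ValueError("config key geometry axes must be positive")
        if not (0 < self.synth.summed_fraction < 1):
            raise ValueError("config key synth.summed_fraction must lie in (0, 1)")


_SECTION_TYPES = {f.name: f for f in dataclasses.fields(RunConfig)}


def _build_section(cls, data: dict, prefix: str):
    known = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            raise ValueError(f"unknown config key: {prefix}{key}")
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; unknown keys are rejected by name."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    kwargs = {}
    for key, value in raw.items():
        if key not in _SECTION_TYPES:
            raise ValueError(f"unknown config key: {key}")
        f = _SECTION_TYPES[key]
        if dataclasses.is_dataclass(f.type) or key in (
            "geometry", "placement", "transport", "sweep", "oracle", "synth", "stats",
        ):
            if not isinstance(value, dict):
                raise ValueError(f"config section {key} must be a mapping")
            cls = f.default_factory()
            kwargs[key] = _build_section(type(cls), value, prefix=f"{key}.")
        else:
            kwargs[key] = value
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def resolve_and_write(cfg: RunConfig, out_dir) -> Path:
    """Write the fully resolved config next to the run outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "resolved_config.yaml"
    path.write_text(yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=False))
    return path
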