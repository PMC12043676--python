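"""Run configuration: YAML schema, validation and defaults.

A single YAML file drives the whole pipeline.  Unknown keys are rejected
so typos fail loudly before any compute starts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .protocol import DEFAULT_PULSE_WIDTHS_US

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config"]


class ConfigError(ValueError):
    pass


@dataclass
class PhantomSection:
    radius: float = 40.0
    length: float = 120.0
    spacing: float = 1.0
    air_margin: float = 4.0


@dataclass
class ElectrodeSection:
    separation: float = 20.0
    radius: float = 3.0
    thickness: float = 2.0


@dataclass
class NerveSection:
    name: str = "median"
    depth: float = 5.5


@dataclass
class PulseSection:
    widths_us: list = field(default_factory=lambda: list(DEFAULT_PULSE_WIDTHS_US))
    interphase_ms: float = 0.1
    polarity: str = "cathodic_first"


@dataclass
class AxonSection:
    diameter: float = 5.7
    n_nodes: int = 101
    variant: str = "sensory"


@dataclass
class SolverSection:
    tol: float = 1e-8


@dataclass
class TitrationSection:
    tol: float = 0.01
    baseline_mA: float = 5.0
    duration_ms: float = 3.5
    dt_ms: float = 0.0025


@dataclass
class RunConfig:
    phantom: PhantomSection = field(default_factory=PhantomSection)
    electrodes: ElectrodeSection = field(default_factory=ElectrodeSection)
    nerves: list = field(default_factory=lambda: [NerveSection()])
    pulse: PulseSection = field(default_factory=PulseSection)
    axon: AxonSection = field(default_factory=AxonSection)
    solver: SolverSection = field(default_factory=SolverSection)
    titration: TitrationSection = field(default_factory=TitrationSection)
    seed: int = 0
    output_dir: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {
    "phantom": PhantomSection,
    "electrodes": ElectrodeSection,
    "pulse": PulseSection,
    "axon": AxonSection,
    "solver": SolverSection,
    "titration": TitrationSection,
}


def _build(cls, data: dict, where: str):
    if not isinstance(data, dict):
        raise ConfigError(f"section {where!r} must be a mapping")
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where!r}: {sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    top_allowed = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - top_allowed
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    kwargs = {}
    for key, cls in _SECTIONS.items():
        if key in data:
            kwargs[key] = _build(cls, data[key], key)
    if "nerves" in data:
        nerves = data["nerves"]
        if not isinstance(nerves, list) or not nerves:
            raise ConfigError("'nerves' must be a non-empty list")
        kwargs["nerves"] = [_build(NerveSection, n, f"nerves[{i}]") for i, n in enumerate(nerves)]
    for key in ("seed", "output_dir"):
        if key in data:
            kwargs[key] = data[key]
    cfg = RunConfig(**kwargs)
    _validate(cfg)
    return cfg


def _validate(cfg: RunConfig) -> None:
    if cfg.phantom.spacing <= 0:
        raise ConfigError("phantom.spacing must be > 0")
    if any(w <= 0 for w in cfg.pulse.widths_us):
        raise ConfigError("pulse.widths_us must all be > 0")
    if len(cfg.pulse.widths_us) < 2:
        raise ConfigError("pulse.widths_us needs at least 2 entries")
    if cfg.titration.baseline_mA <= 0:
        raise ConfigError("titration.baseline_mA must be > 0")
    for nerve in cfg.nerves:
        if not 0 < nerve.depth < cfg.phantom.radius:
            raise ConfigError(
                f"nerve {nerve.name!r} depth {nerve.depth} outside the phantom"
            )


def load_config(path: str | Path) -> RunConfig:
    """Parse and schema-validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    return config_from_dict(data)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
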