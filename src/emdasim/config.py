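"""YAML run configuration.

A single document with ``phantom:``, ``solve:`` and ``biophysics:``
blocks plus top-level ``output_dir``, ``log_level`` and ``seed``.  All
keys are optional (the fully-defaulted config is the default study
condition); unknown keys are rejected so typos cannot silently fall back
to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .biophysics import CellModel, RegimeThresholds
from .phantom import BalloonSpec, HelixSpec, PatchSpec, PhantomParams

__all__ = ["SolveParams", "BiophysicsParams", "RunConfig", "load_config"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SolveParams:
    current_A: float = 0.020
    tol: float = 1e-8
    contact_conductance_S_per_m2: float = 2.0

    def __post_init__(self) -> None:
        if self.current_A <= 0 or self.tol <= 0 or self.contact_conductance_S_per_m2 <= 0:
            raise ConfigError("solve parameters must be > 0")


@dataclass(frozen=True)
class BiophysicsParams:
    thresholds: RegimeThresholds = field(default_factory=RegimeThresholds)
    cells: tuple[CellModel, ...] = (CellModel(),)


@dataclass(frozen=True)
class RunConfig:
    phantom: PhantomParams = field(default_factory=PhantomParams)
    solve: SolveParams = field(default_factory=SolveParams)
    biophysics: BiophysicsParams = field(default_factory=BiophysicsParams)
    output_dir: str = "emda_out"
    log_level: str = "INFO"
    seed: int = 0


def _build(cls, data: dict, where: str):
    """Construct a (possibly nested) dataclass, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigError(f"{where}: expected a mapping, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")
    kwargs = {}
    nested = {
        "helix": HelixSpec, "patches": PatchSpec, "balloon": BalloonSpec,
        "thresholds": RegimeThresholds,
        "phantom": PhantomParams, "solve": SolveParams, "biophysics": BiophysicsParams,
    }
    for key, value in data.items():
        if key in nested and isinstance(value, dict):
            kwargs[key] = _build(nested[key], value, f"{where}.{key}")
        elif key == "cells":
            kwargs[key] = tuple(
                _build(CellModel, c, f"{where}.cells[{i}]") for i, c in enumerate(value)
            )
        elif isinstance(value, list):
            kwargs[key] = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def load_config(path: str | Path | None = None, text: str | None = None) -> RunConfig:
    """Parse a YAML config file (or literal text) into a RunConfig."""
    if text is None:
        text = Path(path).read_text() if path is not None else ""
    data = yaml.safe_load(text) or {}
    cfg = _build(RunConfig, data, "config")
    return cfg


def dump_config(cfg: RunConfig) -> str:
    """Resolved configuration as YAML (for run-snapshot files)."""
    return yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=False)
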