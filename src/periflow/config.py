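"""Structured run configuration: YAML (or JSON) loading, validation, saving.

One config file drives every subcommand.  The ``model`` section is always
required; the remaining sections carry defaults and are validated only when
the invoked subcommand needs them.  Unknown keys are rejected everywhere so
typos fail loudly instead of silently falling back to defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .model import DEFAULT_RTOL, DEFAULT_ATOL
from .rates import RateSchedule

__all__ = ["RunConfig", "load_config", "save_config"]


def _reject_unknown(section: str, d: dict, allowed: set) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown keys in '{section}': {sorted(unknown)}")


@dataclass
class SimulationConfig:
    x0: Optional[list] = None  # default: all sites half full
    t0: float = 0.0
    t_final: float = 100.0
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL
    sample_spacing: Optional[float] = None

    KEYS = {"x0", "t0", "t_final", "rtol", "atol", "sample_spacing"}


@dataclass
class OrbitConfig:
    tol: float = 1e-10
    max_iter: int = 500
    samples_per_period: int = 400

    KEYS = {"tol", "max_iter", "samples_per_period"}


@dataclass
class ContractionConfig:
    epsilon: float = 0.1
    rho: float = 0.5
    time_points: int = 64

    KEYS = {"epsilon", "rho", "time_points"}


@dataclass
class TasepConfig:
    footprint: int = 1
    dt: Optional[float] = None
    t_final: float = 1000.0
    seed: int = 0
    segment_length: Optional[float] = None
    replicates: int = 5

    KEYS = {"footprint", "dt", "t_final", "seed", "segment_length", "replicates"}


@dataclass
class RunConfig:
    """Validated configuration tree for a single run."""

    n: int
    schedule: RateSchedule
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    orbit: OrbitConfig = field(default_factory=OrbitConfig)
    contraction: ContractionConfig = field(default_factory=ContractionConfig)
    tasep: TasepConfig = field(default_factory=TasepConfig)
    seed: int = 0

    def x0(self) -> np.ndarray:
        if self.simulation.x0 is None:
            return np.full(self.n, 0.5)
        x0 = np.asarray(self.simulation.x0, dtype=float)
        if x0.shape != (self.n,):
            raise ValueError(f"x0 must have length n = {self.n}")
        return x0

    def to_dict(self) -> dict:
        d = {
            "model": self.schedule.to_dict(),
            "seed": self.seed,
            "simulation": asdict(self.simulation),
            "orbit": asdict(self.orbit),
            "contraction": asdict(self.contraction),
            "tasep": asdict(self.tasep),
        }
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        _reject_unknown(
            "config",
            raw,
            {"model", "seed", "simulation", "orbit", "contraction", "tasep"},
        )
        if "model" not in raw:
            raise ValueError("config requires a 'model' section (n and rates)")
        schedule = RateSchedule.from_dict(raw["model"])

        def build(name, klass):
            sec = raw.get(name, {}) or {}
            _reject_unknown(name, sec, klass.KEYS)
            return klass(**sec)

        return cls(
            n=schedule.n,
            schedule=schedule,
            simulation=build("simulation", SimulationConfig),
            orbit=build("orbit", OrbitConfig),
            contraction=build("contraction", ContractionConfig),
            tasep=build("tasep", TasepConfig),
            seed=int(raw.get("seed", 0)),
        )


def load_config(path) -> RunConfig:
    """Parse and validate a YAML (or JSON — a YAML subset) config file."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return RunConfig.from_dict(raw)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
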