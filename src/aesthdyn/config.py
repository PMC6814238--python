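"""Experiment-design and population configuration.

The default :class:`SimulationConfig` reproduces the study design the analysis
modules assume: two groups of 25 observers (*rate* and *view*), 15 dance and
15 landscape clips of 30 s each, continuous ratings sampled at 10 Hz (300
samples per clip), ratings on a [-1, 1] scale, and a test plus a retest
session on the same stimuli.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

__all__ = ["Dist", "SimulationConfig", "PipelineConfig"]


@dataclass(frozen=True)
class Dist:
    """A named scalar population distribution.

    kind: one of ``constant``, ``uniform``, ``normal``, ``lognormal``.
    params: distribution parameters —
        constant: (value,); uniform: (low, high); normal: (mean, sd);
        lognormal: (mu, sigma) of the underlying normal.
    """

    kind: str
    params: tuple[float, ...]

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "constant":
            return np.full(size, float(self.params[0]))
        if self.kind == "uniform":
            return rng.uniform(self.params[0], self.params[1], size)
        if self.kind == "normal":
            return rng.normal(self.params[0], self.params[1], size)
        if self.kind == "lognormal":
            return rng.lognormal(self.params[0], self.params[1], size)
        raise ValueError(f"unknown distribution kind: {self.kind!r}")

    def to_dict(self) -> dict[str, Any]:
        return {"kind": self.kind, "params": list(self.params)}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Dist":
        return cls(kind=d["kind"], params=tuple(float(p) for p in d["params"]))


def _default_population() -> dict[str, Dist]:
    # Population heterogeneity of the simulated observers.  Ranges are chosen
    # to span the qualitative continuum the analyses are sensitive to:
    # "fast responders" (small tau, small dead zone) through "slow
    # integrators", mixed shared-taste weights, and a wide spread of
    # session-to-session noise so reliability genuinely varies by person.
    return {
        "w_shared": Dist("uniform", (0.2, 0.8)),
        "tau_integration": Dist("lognormal", (0.0, 0.7)),  # median 1 s
        "dead_zone": Dist("uniform", (0.01, 0.10)),
        "session_noise_sd": Dist("uniform", (0.05, 0.40)),
        "overall_noise_sd": Dist("uniform", (0.05, 0.15)),
        "mean_bias": Dist("normal", (0.0, 0.25)),
        "affinity": Dist("normal", (0.0, 0.25)),
    }


@dataclass
class SimulationConfig:
    """Full description of one simulated experiment.

    All randomness downstream is a pure function of ``rng_seed``.
    """

    n_rate: int = 25
    n_view: int = 25
    n_dance: int = 15
    n_landscape: int = 15
    duration_s: float = 30.0
    sample_rate_hz: float = 10.0
    rng_seed: int = 0

    # latent-trace process
    latent_length_scale_s: float = 3.0   # Gaussian smoothing length scale
    latent_amplitude: float = 0.4        # SD of shared/individual components
    stim_level_sd: float = 0.2           # SD of per-stimulus mean level
    category_shift: float = 0.2          # landscape mean minus dance mean

    population: dict[str, Dist] = field(default_factory=_default_population)

    def __post_init__(self) -> None:
        if min(self.n_rate, self.n_view, self.n_dance, self.n_landscape) < 1:
            raise ValueError("all design counts must be >= 1")
        if self.duration_s <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("duration_s and sample_rate_hz must be positive")
        for name in _default_population():
            if name not in self.population:
                raise ValueError(f"population distribution missing: {name}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate_hz))

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["population"] = {k: v.to_dict() for k, v in self.population.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        d = dict(d)
        pop = d.get("population")
        if pop is not None:
            d["population"] = {k: Dist.from_dict(v) for k, v in pop.items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        """Stable hash of the configuration, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineConfig:
    """Orchestration options for :func:`aesthdyn.pipeline.run_pipeline`."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    out_dir: str = "results"
    force: bool = False
    stages: tuple[str, ...] = (
        "reliability", "variability", "agreement", "inference",
    )
    log_level: str = "INFO"

    def to_dict(self) -> dict[str, Any]:
        return {
            "simulation": self.simulation.to_dict(),
            "out_dir": self.out_dir,
            "force": self.force,
            "stages": list(self.stages),
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        sim = d.get("simulation", {})
        return cls(
            simulation=SimulationConfig.from_dict(sim)
            if not isinstance(sim, SimulationConfig) else sim,
            out_dir=d.get("out_dir", "results"),
            force=bool(d.get("force", False)),
            stages=tuple(d.get(
                "stages",
                ("reliability", "variability", "agreement", "inference"))),
            log_level=d.get("log_level", "INFO"),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def validate_finite(**named: float) -> None:
    for name, value in named.items():
        if not math.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value!r}")
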