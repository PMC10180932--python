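"""Simulation configuration: physical and numerical parameters of a run.

Reduced units throughout: the spring constant ``k``, bead friction ``f``
and thermal energy ``kBT`` set the length scale ``sqrt(kBT/k)`` and time
scale ``f/k``; all other quantities are expressed in these units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any

import yaml

__all__ = ["SimulationConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class SimulationConfig:
    """All parameters of a Brownian-dynamics run of a sheared bead-spring chain.

    Parameters
    ----------
    n_beads
        Number of beads N in the chain (>= 2).
    spring_constant
        Hookean constant k of each bead-bead spring (force/length).
    friction
        Bead friction coefficient f (force*time/length).
    thermal_energy
        kBT; sets the amplitude of the random thermal displacements.
    time_step
        Integration step dt.
    shear_rate
        Velocity gradient G = dv_x/dy of the imposed linear flow (1/time).
        The drift it induces is measured from the instantaneous chain
        center of mass, so the flow exerts no net force on the chain.
    n_production_steps
        Steps advanced while recording.
    n_thermalization_steps
        Steps advanced (and discarded) before production so that sampled
        statistics are stationary.
    sample_stride
        A frame is recorded every ``sample_stride`` steps.
    seed
        Seed for the Gaussian thermal-displacement stream.
    """

    n_beads: int = 16
    spring_constant: float = 1.0
    friction: float = 1.0
    thermal_energy: float = 1.0
    time_step: float = 1.0e-3
    shear_rate: float = 0.0
    n_production_steps: int = 2_000_000
    n_thermalization_steps: int = 200_000
    sample_stride: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_beads < 2:
            raise ValueError(f"n_beads must be >= 2, got {self.n_beads}")
        if self.spring_constant < 0 or self.friction < 0 or self.thermal_energy < 0:
            raise ValueError("spring_constant, friction and thermal_energy must be >= 0")
        if self.time_step <= 0:
            raise ValueError(f"time_step must be > 0, got {self.time_step}")
        if self.sample_stride < 1:
            raise ValueError(f"sample_stride must be >= 1, got {self.sample_stride}")
        if self.n_production_steps < 0 or self.n_thermalization_steps < 0:
            raise ValueError("step counts must be >= 0")
        if not math.isfinite(self.noise_scale):
            raise ValueError("derived noise scale sqrt(2*kBT*dt/f) is not finite")

    @property
    def noise_scale(self) -> float:
        """Per-component std of the thermal step, dr = sqrt(2*kBT*dt/f).

        An athermal chain (kBT = 0) has zero noise whatever the friction;
        kBT > 0 with f = 0 has no finite overdamped limit.
        """
        if self.thermal_energy == 0:
            return 0.0
        if self.friction == 0:
            return math.inf
        return math.sqrt(2.0 * self.thermal_energy * self.time_step / self.friction)

    @property
    def n_frames(self) -> int:
        """Frames recorded in production: floor(n_production_steps / stride).

        The initial (post-thermalization) configuration is *not* stored;
        frame j holds the state after production step ``(j+1)*stride``.
        """
        return self.n_production_steps // self.sample_stride

    def replace(self, **changes: Any) -> "SimulationConfig":
        return replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def digest(self) -> str:
        """Short stable hash of the parameter set, for file provenance."""
        import hashlib

        text = ",".join(f"{k}={v!r}" for k, v in sorted(self.to_dict().items()))
        return hashlib.sha256(text.encode()).hexdigest()[:12]


_FIELD_NAMES = {f.name for f in fields(SimulationConfig)}


def load_config(path: str | Path, **overrides: Any) -> SimulationConfig:
    """Read a flat key-value (YAML) config file; keyword overrides win.

    Raises ``KeyError`` naming the first unknown key.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a key-value mapping")
    for key in data:
        if key not in _FIELD_NAMES:
            raise KeyError(f"unknown config key {key!r} in {path}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return SimulationConfig(**data)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
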