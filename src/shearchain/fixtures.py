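"""Synthetic inputs with known ground truth for validating the diagnostics.

None of these touch the physical simulator: the rigid-motion generator
exercises the rotation estimator against an exactly known angular rate,
the Ornstein-Uhlenbeck generator exercises the correlation estimator and
exponential fits against a known decay rate, and the single-mode chain
exercises the eigenvector property of the spring dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig
from .simulator import ChainState, Trajectory

__all__ = [
    "RigidMotionSpec",
    "OUSpec",
    "make_rigid_trajectory",
    "make_ou_series",
    "make_single_mode_chain",
]

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class RigidMotionSpec:
    """A rigid shape rotating at a fixed rate about one axis while translating.

    The generated frames are exact rigid rotations of ``base_shape`` (all
    inter-bead distances preserved to machine precision).  The recorded
    per-frame "single-step displacements" are the instantaneous rigid-body
    velocities times ``time_step`` — the ideal limit of a vanishing
    integration step — so the angular-momentum estimator recovers
    ``angular_rate`` exactly rather than through a finite-angle chord.
    """

    base_shape: np.ndarray  # (N, 3)
    angular_rate: float = 0.0
    rotation_axis: str = "z"
    translation_velocity: tuple = (0.0, 0.0, 0.0)
    time_step: float = 1.0e-3
    n_frames: int = 100

    def __post_init__(self) -> None:
        shape = np.asarray(self.base_shape, dtype=float)
        if shape.ndim != 2 or shape.shape[1] != 3 or shape.shape[0] < 1:
            raise ValueError("base_shape must be a non-empty (N, 3) array")
        if self.rotation_axis not in _AXIS_INDEX:
            raise ValueError(f"rotation_axis must be x, y or z, got {self.rotation_axis!r}")
        object.__setattr__(self, "base_shape", shape)


def _rotation_matrix(axis: str, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    if axis == "x":
        return np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])
    return np.array([[c, 0, s], [0, 1.0, 0], [-s, 0, c]])


def make_rigid_trajectory(spec: RigidMotionSpec) -> Trajectory:
    """Frames of the rotating, translating rigid shape with exact velocities."""
    n_beads = spec.base_shape.shape[0]
    dt = spec.time_step
    v_trans = np.asarray(spec.translation_velocity, dtype=float)
    omega_vec = np.zeros(3)
    omega_vec[_AXIS_INDEX[spec.rotation_axis]] = spec.angular_rate

    times = dt * np.arange(1, spec.n_frames + 1)
    positions = np.empty((spec.n_frames, n_beads, 3))
    displacements = np.empty_like(positions)
    for f, t in enumerate(times):
        rot = _rotation_matrix(spec.rotation_axis, spec.angular_rate * t)
        r = spec.base_shape @ rot.T + v_trans * t
        positions[f] = r
        # instantaneous velocity: omega x (r - com) + v_trans
        rel = r - r.mean(axis=0)
        displacements[f] = dt * (np.cross(omega_vec, rel) + v_trans)

    config = SimulationConfig(
        n_beads=max(n_beads, 2),
        time_step=dt,
        shear_rate=0.0,
        n_production_steps=spec.n_frames,
        n_thermalization_steps=0,
        sample_stride=1,
        seed=0,
    )
    return Trajectory(positions, times, config, displacements)


@dataclass(frozen=True)
class OUSpec:
    """An Ornstein-Uhlenbeck process: decay ``rate``, target ``variance``.

    ``rate == 0`` degenerates to a driven random walk whose per-step
    variance is ``2 * variance * time_step`` (``variance`` then plays the
    role of a diffusivity), so the series' variance grows linearly in time.
    """

    rate: float
    variance: float
    time_step: float = 1.0e-2
    length: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"rate must be >= 0, got {self.rate}")
        if self.variance < 0:
            raise ValueError(f"variance must be >= 0, got {self.variance}")


def make_ou_series(spec: OUSpec) -> np.ndarray:
    """Exact-discretization OU series: a' = a e^(-rate dt) + matched noise.

    Exact discretization (not Euler) so the ground truth — autocorrelation
    variance * exp(-rate * lag) — holds at any time step, independent of
    the simulator's integration error.  The first sample is drawn from the
    stationary distribution.
    """
    rng = np.random.default_rng(spec.seed)
    out = np.empty(spec.length)
    if spec.rate > 0:
        rho = np.exp(-spec.rate * spec.time_step)
        step_std = np.sqrt(spec.variance * (1.0 - rho**2))
        out[0] = rng.normal(0.0, np.sqrt(spec.variance))
        for i in range(1, spec.length):
            out[i] = rho * out[i - 1] + step_std * rng.normal()
    else:
        steps = rng.normal(0.0, np.sqrt(2.0 * spec.variance * spec.time_step), spec.length)
        steps[0] = 0.0
        out = np.cumsum(steps)
    return out


def make_single_mode_chain(n_beads: int, n: int, amplitude: float) -> ChainState:
    """A chain whose x-coordinates carry exactly one Rouse mode.

    x_i = 2 * amplitude * cos(n pi (i - 1/2) / N), y = z = 0: the forward
    transform returns ``amplitude`` at mode n and zero elsewhere, and the
    spring drift maps the configuration onto -Gamma_n times itself
    (eigenvector property).
    """
    if not 1 <= n <= n_beads - 1:
        raise ValueError(f"mode index must be in [1, {n_beads - 1}], got {n}")
    i = np.arange(1, n_beads + 1)
    positions = np.zeros((n_beads, 3))
    positions[:, 0] = 2.0 * amplitude * np.cos(n * np.pi * (i - 0.5) / n_beads)
    return ChainState(positions)
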