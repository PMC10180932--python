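"""Overdamped Brownian dynamics of a harmonic bead-spring chain in shear.

The chain is free-draining: each bead feels its own friction f, Hookean
spring forces from its neighbours, an imposed linear shear flow, and an
independent Gaussian thermal kick.  The equations of motion for the bead
positions R_i are

    dR_i/dt = -(k/f) (2 R_i - R_{i-1} - R_{i+1}) + G (y_i - y_cm) x_hat + F_i(t)

with one-sided spring terms for the two end beads.  The shear drift is
measured from the instantaneous center of mass, so the flow describes
chain motion relative to the chain center and imparts no net force.

Integration is explicit Euler-Maruyama: each step displaces the beads by
dt times the deterministic drift plus an i.i.d. Gaussian displacement of
per-component standard deviation dr = sqrt(2 kBT dt / f).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import SimulationConfig

try:  # pragma: no cover - exercised implicitly by every simulation test
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


logger = logging.getLogger(__name__)

__all__ = [
    "ChainState",
    "Trajectory",
    "DivergenceError",
    "spring_drift",
    "shear_drift",
    "thermal_displacement",
    "step",
    "simulate",
    "connectivity_matrix",
    "initial_configuration",
]

_LOG_INTERVAL = 100_000  # steps between progress log lines


class DivergenceError(RuntimeError):
    """Raised when bead positions become non-finite (time step too large)."""

    def __init__(self, step_index: int):
        self.step_index = step_index
        super().__init__(
            f"non-finite bead positions at step {step_index}; "
            "the time step is likely too large for this spring constant / friction"
        )


@dataclass(frozen=True)
class ChainState:
    """Bead positions of one chain at one instant."""

    positions: np.ndarray  # (N, 3)
    time: float = 0.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] < 1:
            raise ValueError(f"positions must be (N, 3), got shape {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        object.__setattr__(self, "positions", pos)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class Trajectory:
    """Sampled frames of a run: positions, single-step displacements, times.

    ``displacements[j]`` is the displacement accumulated during the single
    time step that produced frame j (new minus old positions at that step),
    *not* the difference between consecutive stored frames: frames are
    ``sample_stride`` steps apart, and the rotation diagnostics need the
    instantaneous velocity proxy displacement/dt.  A trajectory from a
    source that cannot supply per-step displacements stores ``None`` there.
    """

    positions: np.ndarray  # (F, N, 3)
    times: np.ndarray  # (F,)
    config: SimulationConfig
    displacements: np.ndarray | None = None  # (F, N, 3)

    def __post_init__(self) -> None:
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (F, N, 3)")
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions disagree on frame count")
        if self.displacements is not None and self.displacements.shape != self.positions.shape:
            raise ValueError("displacements must match positions in shape")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_beads(self) -> int:
        return self.positions.shape[1]

    @property
    def frame_spacing(self) -> float:
        """Time between stored frames: sample_stride * dt."""
        return self.config.sample_stride * self.config.time_step

    def com(self) -> np.ndarray:
        """(F, 3) center-of-mass position per frame (equal bead masses)."""
        return self.positions.mean(axis=1)

    def centered_positions(self) -> np.ndarray:
        """(F, N, 3) positions relative to the per-frame center of mass."""
        return self.positions - self.com()[:, None, :]

    def centered_displacements(self) -> np.ndarray:
        """Single-step displacements relative to the COM displacement.

        Raises ``ValueError`` if the displacement channel is absent; the
        per-step displacements cannot be reconstructed from stride-separated
        frames.
        """
        if self.displacements is None:
            raise ValueError(
                "trajectory carries no single-step displacements; they cannot be "
                "substituted by differences of stride-separated frames"
            )
        return self.displacements - self.displacements.mean(axis=1)[:, None, :]

    def frame(self, j: int) -> ChainState:
        return ChainState(self.positions[j], float(self.times[j]))


def connectivity_matrix(n_beads: int) -> np.ndarray:
    """The tridiagonal Rouse connectivity matrix M (free ends).

    ``spring_drift(R) == -(k/f) * M @ R`` row-wise; M has 2 on the interior
    diagonal, 1 at the two corners, and -1 on the off-diagonals.
    """
    if n_beads < 2:
        raise ValueError(f"a chain needs at least 2 beads, got {n_beads}")
    m = 2.0 * np.eye(n_beads) - np.eye(n_beads, k=1) - np.eye(n_beads, k=-1)
    m[0, 0] = 1.0
    m[-1, -1] = 1.0
    return m


def spring_drift(positions: np.ndarray, spring_constant: float, friction: float) -> np.ndarray:
    """Deterministic spring velocity -(k/f)(2R_i - R_{i-1} - R_{i+1}) per bead.

    End beads use the one-sided forms -(k/f)(R_1 - R_2) and
    -(k/f)(R_N - R_{N-1}).  Internal forces cancel: the rows sum to zero.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.shape[0] < 2:
        raise ValueError(f"a chain needs at least 2 beads, got {pos.shape[0]}")
    drift = np.empty_like(pos)
    drift[1:-1] = -(2.0 * pos[1:-1] - pos[:-2] - pos[2:])
    drift[0] = -(pos[0] - pos[1])
    drift[-1] = -(pos[-1] - pos[-2])
    drift *= spring_constant / friction
    return drift


def shear_drift(positions: np.ndarray, shear_rate: float) -> np.ndarray:
    """Drift from the linear flow: x-velocity G*(y_i - y_cm), y and z zero.

    The y-coordinate is measured from the instantaneous center of mass, so
    the mean x-drift over beads is exactly zero.
    """
    pos = np.asarray(positions, dtype=float)
    drift = np.zeros_like(pos)
    drift[:, 0] = shear_rate * (pos[:, 1] - pos[:, 1].mean())
    return drift


def thermal_displacement(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    """One step's Gaussian thermal displacement, std sqrt(2*kBT*dt/f) per axis."""
    return rng.normal(0.0, config.noise_scale, size=(config.n_beads, 3))


def step(
    state: ChainState, config: SimulationConfig, rng: np.random.Generator
) -> tuple[ChainState, np.ndarray]:
    """Advance one Euler-Maruyama step; return the new state and its displacement."""
    drift = spring_drift(state.positions, config.spring_constant, config.friction)
    drift += shear_drift(state.positions, config.shear_rate)
    disp = config.time_step * drift + thermal_displacement(rng, config)
    new_pos = state.positions + disp
    if not np.all(np.isfinite(new_pos)):
        raise DivergenceError(0)
    return ChainState(new_pos, state.time + config.time_step), disp


@njit(cache=True)
def _advance(pos, noise, kf_dt, g_dt, stride, out_pos, out_disp, frame0):  # pragma: no cover
    """Advance len(noise) steps in place, recording every ``stride`` steps.

    ``noise`` holds the pre-generated thermal displacements for this chunk;
    kf_dt = k*dt/f and g_dt = G*dt.  Recording starts at ``frame0`` and the
    step count of this chunk is assumed to be a multiple of ``stride`` when
    out_pos is non-empty.  Returns the number of frames written.
    """
    n_steps = noise.shape[0]
    n = pos.shape[0]
    disp = np.empty((n, 3))
    written = 0
    for s in range(n_steps):
        ycm = 0.0
        for i in range(n):
            ycm += pos[i, 1]
        ycm /= n
        for i in range(n):
            for a in range(3):
                if i == 0:
                    spring = -(pos[0, a] - pos[1, a])
                elif i == n - 1:
                    spring = -(pos[n - 1, a] - pos[n - 2, a])
                else:
                    spring = -(2.0 * pos[i, a] - pos[i - 1, a] - pos[i + 1, a])
                d = kf_dt * spring + noise[s, i, a]
                if a == 0:
                    d += g_dt * (pos[i, 1] - ycm)
                disp[i, a] = d
        pos += disp
        if (s + 1) % stride == 0 and out_pos.shape[0] > 0:
            j = frame0 + written
            out_pos[j] = pos
            out_disp[j] = disp
            written += 1
    return written


def initial_configuration(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Gaussian random-walk start: bond components i.i.d. N(0, kBT/k).

    This is the equilibrium bond distribution at zero shear, so only mild
    thermalization is needed; with kBT = 0 or k = 0 the chain starts
    collapsed at the origin.
    """
    n = config.n_beads
    if config.spring_constant > 0 and config.thermal_energy > 0:
        bond_std = np.sqrt(config.thermal_energy / config.spring_constant)
        bonds = rng.normal(0.0, bond_std, size=(n - 1, 3))
        pos = np.vstack([np.zeros(3), np.cumsum(bonds, axis=0)])
    else:
        pos = np.zeros((n, 3))
    return pos - pos.mean(axis=0)


def simulate(config: SimulationConfig, initial: np.ndarray | None = None) -> Trajectory:
    """Run thermalization then production, recording every ``sample_stride`` steps.

    Each recorded frame stores the positions after that step together with
    that single step's displacement array.  The full run (initial random
    walk, thermal stream) is reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    pos = (
        np.array(initial, dtype=float, copy=True)
        if initial is not None
        else initial_configuration(config, rng)
    )
    if pos.shape != (config.n_beads, 3):
        raise ValueError(f"initial positions must be {(config.n_beads, 3)}, got {pos.shape}")

    kf_dt = config.spring_constant * config.time_step / config.friction
    g_dt = config.shear_rate * config.time_step
    n_frames = config.n_frames
    out_pos = np.empty((n_frames, config.n_beads, 3))
    out_disp = np.empty_like(out_pos)
    empty = np.empty((0, config.n_beads, 3))

    # Chunk the pre-generated noise so memory stays modest and divergence
    # is detected promptly; chunks are stride-aligned so frame recording
    # never straddles a chunk boundary.
    chunk = max(config.sample_stride, (_LOG_INTERVAL // config.sample_stride) * config.sample_stride)

    def run_phase(n_steps: int, record: bool, phase: str) -> None:
        done = 0
        frames_written = 0
        while done < n_steps:
            take = min(chunk, n_steps - done)
            if record:
                take = (take // config.sample_stride) * config.sample_stride
                if take == 0:
                    break  # leftover steps < stride produce no frame
            noise = rng.normal(0.0, config.noise_scale, size=(take, config.n_beads, 3))
            if record:
                frames_written += _advance(
                    pos, noise, kf_dt, g_dt, config.sample_stride, out_pos, out_disp, frames_written
                )
            else:
                _advance(pos, noise, kf_dt, g_dt, take + 1, empty, empty, 0)
            done += take
            if not np.all(np.isfinite(pos)):
                raise DivergenceError(done)
            rg = np.sqrt(((pos - pos.mean(axis=0)) ** 2).sum(axis=1).mean())
            logger.info("%s step %d: radius of gyration %.4f", phase, done, rg)

    run_phase(config.n_thermalization_steps, record=False, phase="thermalization")
    run_phase(config.n_production_steps, record=True, phase="production")

    times = config.time_step * config.sample_stride * np.arange(1, n_frames + 1)
    return Trajectory(out_pos, times, config, out_disp)
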