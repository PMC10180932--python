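"""Rouse normal-mode (discrete cosine) analysis of bead coordinates.

For an N-bead free-draining harmonic chain the collective coordinates

    C_n = (1/N) sum_{i=1..N} x_i cos(n pi (i - 1/2) / N),   n = 0..N-1

diagonalize the spring dynamics: the cosine vectors are the eigenvectors
of the tridiagonal connectivity matrix, so at zero shear each internal
mode relaxes exponentially with the corresponding eigenvalue rate

    Gamma_n = (4k/f) sin^2(n pi / 2N)  ->  k n^2 pi^2 / (f N^2)  as n/N -> 0,

while C_0 is the center-of-mass coordinate with Gamma_0 = 0.  The
inverse is

    x_i = C_0 + 2 sum_{n=1..N-1} C_n cos(n pi (i - 1/2) / N).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .simulator import Trajectory

__all__ = [
    "ModeAmplitudes",
    "ModeRates",
    "forward_transform",
    "inverse_transform",
    "analytic_rates",
    "mode_trajectory",
    "mode_stationary_variance",
    "cosine_basis",
    "modes_to_frame",
]

AXES = ("x", "y", "z")


@dataclass(frozen=True)
class ModeAmplitudes:
    """Rouse coefficients C_{n,alpha} of one frame: (N, 3) array, n x axis."""

    coefficients: np.ndarray
    time: float = 0.0


@dataclass(frozen=True)
class ModeRates:
    """Analytic relaxation rates Gamma_n, n = 0..N-1; Gamma_0 = 0."""

    rates: np.ndarray


@lru_cache(maxsize=8)
def _basis(n_beads: int) -> np.ndarray:
    n = np.arange(n_beads)[:, None]
    i = np.arange(1, n_beads + 1)[None, :]
    return np.cos(n * np.pi * (i - 0.5) / n_beads)


def cosine_basis(n_beads: int) -> np.ndarray:
    """(N, N) matrix B with B[n, i-1] = cos(n pi (i - 1/2) / N)."""
    return _basis(n_beads).copy()


def forward_transform(coordinates: np.ndarray) -> np.ndarray:
    """Mode amplitudes C_n of one axis's bead coordinates (length N >= 2).

    A trailing axis is transformed independently, so an (N, 3) frame maps
    to its (N, 3) coefficient array in one call.
    """
    x = np.asarray(coordinates, dtype=float)
    n_beads = x.shape[0]
    if n_beads < 2:
        raise ValueError(f"need at least 2 beads, got {n_beads}")
    return np.tensordot(_basis(n_beads), x, axes=(1, 0)) / n_beads


def inverse_transform(coefficients: np.ndarray) -> np.ndarray:
    """Bead coordinates from mode amplitudes; exact inverse of the forward map."""
    c = np.asarray(coefficients, dtype=float)
    n_beads = c.shape[0]
    weights = np.full(n_beads, 2.0)
    weights[0] = 1.0
    b = _basis(n_beads)
    return np.tensordot(b.T, weights.reshape((n_beads,) + (1,) * (c.ndim - 1)) * c, axes=(1, 0))


def analytic_rates(config: SimulationConfig) -> ModeRates:
    """Gamma_n = (4k/f) sin^2(n pi / 2N) for n >= 1, Gamma_0 = 0.

    These are exactly the eigenvalues of (k/f) times the chain's
    tridiagonal connectivity matrix, i.e. the relaxation rates of the
    mode autocorrelations <C_n(0) C_n(t)> of the unsheared dynamics.
    (For N = 2 this reduces to the single bond rate 2k/f.)
    """
    if config.friction <= 0:
        raise ValueError("friction must be > 0 for finite relaxation rates")
    n = np.arange(config.n_beads)
    rates = (
        4.0
        * config.spring_constant
        * np.sin(n * np.pi / (2.0 * config.n_beads)) ** 2
        / config.friction
    )
    return ModeRates(rates)


def mode_stationary_variance(config: SimulationConfig) -> np.ndarray:
    """Stationary variance of each internal mode amplitude at zero shear.

    The exact single-step recursion for C_n is an Ornstein-Uhlenbeck
    process driven by the projected thermal kicks, whose per-step variance
    is dr^2/(2N); balancing drive against decay gives

        <C_n^2> = kBT / (2 N f Gamma_n),   n >= 1

    (to leading order in dt).  Index 0 is set to NaN: the center-of-mass
    mode diffuses freely and has no stationary variance.
    """
    rates = analytic_rates(config).rates
    out = np.full(config.n_beads, np.nan)
    out[1:] = config.thermal_energy / (
        2.0 * config.n_beads * config.friction * rates[1:]
    )
    return out


def mode_trajectory(trajectory: Trajectory) -> np.ndarray:
    """(F, N, 3) Rouse amplitudes per frame, from COM-relative coordinates.

    Using COM-relative coordinates makes C_0 identically zero, a useful
    null channel; internal modes (n >= 1) are unaffected by the choice of
    frame because the n >= 1 cosine rows sum to zero.
    """
    centered = trajectory.centered_positions()  # (F, N, 3)
    basis = _basis(trajectory.n_beads)
    modes = np.tensordot(centered, basis, axes=(1, 1))  # (F, 3, N) via GEMM
    return np.ascontiguousarray(modes.transpose(0, 2, 1)) / trajectory.n_beads


def modes_to_frame(trajectory: Trajectory) -> pd.DataFrame:
    """Tidy mode time series: columns (time, n, axis, value)."""
    modes = mode_trajectory(trajectory)
    n_frames, n_beads, _ = modes.shape
    frames = {
        "time": np.repeat(trajectory.times, n_beads * 3),
        "n": np.tile(np.repeat(np.arange(n_beads), 3), n_frames),
        "axis": np.tile(list(AXES), n_frames * n_beads),
        "value": modes.reshape(-1),
    }
    return pd.DataFrame(frames)
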