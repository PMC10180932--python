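"""Spatial Fourier and Haar-wavelet collective coordinates.

Rouse amplitudes are global coordinates: each one mixes every bead.  Two
alternatives are provided.  The spatial Fourier components

    a_{k,alpha}(t) = sum_i cos(k r_{i,alpha}(t))

(COM-relative coordinates) are also global; the Haar wavelet components
are local.  For a chain of N = 2^m beads, level-1 components are the
pairwise means c(1,alpha,j) and half-differences d(1,alpha,j) of
consecutive bead coordinates; each further level applies the same
mean/half-difference pair to the previous level's means, halving the
channel count, so channel (n, j) describes the collective displacement of
a specific block of 2^n adjacent beads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulator import Trajectory

__all__ = [
    "FourierComponents",
    "WaveletComponents",
    "WaveletSeries",
    "fourier_components",
    "haar_decompose",
    "haar_reconstruct",
    "wavelet_trajectory",
]

DEFAULT_WAVENUMBERS = (0.5, 1.0, 2.0, 4.0)


@dataclass(frozen=True)
class FourierComponents:
    """Per-frame spatial cosine sums: values[f, k, axis], |values| <= N."""

    wavenumbers: np.ndarray
    values: np.ndarray  # (F, K, 3)
    times: np.ndarray

    def series(self, k: float, axis: str) -> np.ndarray:
        ki = int(np.argmin(np.abs(self.wavenumbers - k)))
        return self.values[:, ki, "xyz".index(axis)]


@dataclass(frozen=True)
class WaveletComponents:
    """Haar tree of one frame (or a whole trajectory, with a leading time axis).

    ``levels[n-1]`` is the pair (c, d) at decomposition level n; the
    channel axis has length 2^(m-n).  Remaining axes mirror the input
    (e.g. the Cartesian axis for (N, 3) input).
    """

    levels: tuple

    @property
    def depth(self) -> int:
        return len(self.levels)

    def c(self, n: int) -> np.ndarray:
        return self.levels[n - 1][0]

    def d(self, n: int) -> np.ndarray:
        return self.levels[n - 1][1]


def fourier_components(
    trajectory: Trajectory, wavenumbers=DEFAULT_WAVENUMBERS
) -> FourierComponents:
    """sum_i cos(k * r_{i,alpha}) per frame, axis and wavenumber (COM-relative)."""
    k = np.asarray(wavenumbers, dtype=float)
    if not np.all(np.isfinite(k)):
        raise ValueError("wavenumbers must be finite")
    r = trajectory.centered_positions()  # (F, N, 3)
    values = np.cos(k[None, :, None, None] * r[:, None, :, :]).sum(axis=2)
    return FourierComponents(k, values, trajectory.times)


def _check_power_of_two(n: int) -> int:
    m = n.bit_length() - 1
    if n < 2 or (1 << m) != n:
        raise ValueError(
            f"Haar decomposition needs a power-of-two bead count, got {n}"
        )
    return m


def haar_decompose(coordinates: np.ndarray, channel_axis: int = 0) -> WaveletComponents:
    """Full Haar pyramid of bead coordinates along ``channel_axis``.

    At each level the channel with 1-based index j holds the mean (c) and
    half-difference (d) of the previous level's channels 2j-1 and 2j;
    level 1 acts on the bead coordinates themselves.  The bead count along
    ``channel_axis`` must be a power of two.
    """
    x = np.asarray(coordinates, dtype=float)
    x = np.moveaxis(x, channel_axis, 0)
    m = _check_power_of_two(x.shape[0])
    levels = []
    prev = x
    for _ in range(m):
        c = 0.5 * (prev[0::2] + prev[1::2])
        d = 0.5 * (prev[1::2] - prev[0::2])
        levels.append(
            (np.moveaxis(c, 0, channel_axis), np.moveaxis(d, 0, channel_axis))
        )
        prev = c
    return WaveletComponents(tuple(levels))


def haar_reconstruct(components: WaveletComponents, channel_axis: int = 0) -> np.ndarray:
    """Exact inverse of ``haar_decompose`` (machine precision).

    Uses the deepest level's c together with every level's d; channel
    2j-1 = c - d and channel 2j = c + d, unwound from the top.
    """
    depth = components.depth
    prev = np.moveaxis(np.asarray(components.c(depth), dtype=float), channel_axis, 0)
    for n in range(depth, 0, -1):
        c = np.moveaxis(np.asarray(components.c(n), dtype=float), channel_axis, 0)
        d = np.moveaxis(np.asarray(components.d(n), dtype=float), channel_axis, 0)
        if c.shape != d.shape or c.shape[0] != prev.shape[0]:
            raise ValueError(f"inconsistent component shapes at level {n}")
        lower = np.empty((2 * c.shape[0],) + c.shape[1:], dtype=float)
        lower[0::2] = prev - d
        lower[1::2] = prev + d
        prev = lower
    return np.moveaxis(prev, 0, channel_axis)


@dataclass(frozen=True)
class WaveletSeries:
    """Haar components of every frame of a trajectory.

    ``components.c(n)`` and ``.d(n)`` have shape (F, 2^(m-n), 3); channel
    index j is 1-based in :meth:`channel`, matching the left-to-right bead
    order (j = 1 is the chain's first-bead end).
    """

    components: WaveletComponents
    times: np.ndarray

    def channel(self, family: str, n: int, axis: str, j: int) -> np.ndarray:
        arr = self.components.c(n) if family == "c" else self.components.d(n)
        return arr[:, j - 1, "xyz".index(axis)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for n in range(1, self.components.depth + 1):
            for family in ("c", "d"):
                arr = self.components.c(n) if family == "c" else self.components.d(n)
                n_ch = arr.shape[1]
                for j in range(1, n_ch + 1):
                    for a, ax in enumerate("xyz"):
                        rows.append(
                            pd.DataFrame(
                                {
                                    "time": self.times,
                                    "family": family,
                                    "level": n,
                                    "axis": ax,
                                    "j": j,
                                    "value": arr[:, j - 1, a],
                                }
                            )
                        )
        return pd.concat(rows, ignore_index=True)


def wavelet_trajectory(trajectory: Trajectory) -> WaveletSeries:
    """Haar decomposition of every frame's COM-relative coordinates."""
    centered = trajectory.centered_positions()  # (F, N, 3)
    comps = haar_decompose(centered, channel_axis=1)
    return WaveletSeries(comps, trajectory.times)
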