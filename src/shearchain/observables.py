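"""Shape, distance and whole-body-rotation diagnostics of chain trajectories.

All diagnostics work on coordinates relative to the instantaneous chain
center of mass.  The rotation estimator is the angular-momentum ratio

    omega_z * sum_i <x_i^2 + y_i^2> = < sum_i x_i dy_i/dt - y_i dx_i/dt >

with the bead velocities replaced by the recorded single-step
displacements divided by dt, and cyclic analogues for the x and y axes.
A chain advected by a shear flow dv_x/dy = G > 0 rotates clockwise in the
x-y plane (omega_z < 0); for an undistorted coil the torque balance gives
omega_z = -G <y^2> / <x^2 + y^2> ~ -G/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correlations import CorrelationFunction, block_error, correlate
from .simulator import Trajectory

__all__ = [
    "ShapeMoments",
    "AxisRotation",
    "RotationDiagnostics",
    "Histogram",
    "DistanceDistributions",
    "shape_moments",
    "rotation_diagnostics",
    "end_to_end_correlations",
    "distance_distributions",
    "com_msd",
]

# rotation about `axis` mixes the two transverse coordinates (a, b),
# ordered so that L = sum x_a * v_b - x_b * v_a has the right-hand sign
_TRANSVERSE = {"x": (1, 2), "y": (2, 0), "z": (0, 1)}


@dataclass(frozen=True)
class ShapeMoments:
    """Bead-distribution moments around the center of mass.

    ``second[a, b] = <x_a x_b>`` and ``fourth[a, b] = <x_a^2 x_b^2>``,
    averaged over all beads and all frames; ``rg2`` is the mean-square
    radius of gyration, the trace of ``second``.  ``second_err`` holds
    block-averaging standard errors for the second moments.
    """

    second: np.ndarray
    fourth: np.ndarray
    rg2: float
    second_err: np.ndarray | None = None


@dataclass(frozen=True)
class AxisRotation:
    """Rotation diagnostics about one axis.

    ``term_ab`` and ``term_ba`` are the time averages of the two sums in
    the angular-momentum estimator (for the z axis: sum_i x_i dy_i/dt and
    sum_i y_i dx_i/dt); ``L = term_ab - term_ba`` is the nominal angular
    motion, ``moment`` the time-averaged transverse moment
    sum_i <x_a^2 + x_b^2>, and ``omega = L / moment`` — a ratio of time
    averages, not an average of per-frame ratios.  ``*_err`` are block
    standard errors (omega's from per-block ratios).
    """

    axis: str
    term_ab: float
    term_ba: float
    L: float
    moment: float
    omega: float
    term_ab_err: float
    term_ba_err: float
    L_err: float
    omega_err: float


@dataclass(frozen=True)
class RotationDiagnostics:
    x: AxisRotation
    y: AxisRotation
    z: AxisRotation

    def __getitem__(self, axis: str) -> AxisRotation:
        return getattr(self, axis)


@dataclass(frozen=True)
class Histogram:
    edges: np.ndarray
    counts: np.ndarray

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class DistanceDistributions:
    nearest_neighbor: Histogram
    second_nearest_neighbor: Histogram
    end_to_end: Histogram
    bead_to_com: Histogram
    all_pairs: Histogram


def shape_moments(trajectory: Trajectory, n_blocks: int = 20) -> ShapeMoments:
    """Second and fourth moments of COM-relative coordinates (beads x frames)."""
    if trajectory.n_frames < 1:
        raise ValueError("need at least one frame")
    centered = trajectory.centered_positions()
    count = trajectory.n_frames * trajectory.n_beads
    r = centered.reshape(-1, 3)
    second = (r.T @ r) / count
    r2 = r**2
    fourth = (r2.T @ r2) / count
    comps = [np.ascontiguousarray(centered[:, :, k]) for k in range(3)]
    del centered, r, r2
    err = np.zeros((3, 3))
    if trajectory.n_frames >= n_blocks:
        for a in range(3):
            for b in range(a, 3):
                per_frame = np.einsum("fi,fi->f", comps[a], comps[b]) / trajectory.n_beads
                err[a, b] = err[b, a] = block_error(per_frame, n_blocks)
    return ShapeMoments(second, fourth, float(np.trace(second)), err)


def _axis_rotation(
    axis: str, pos: list[np.ndarray], vel: list[np.ndarray], n_blocks: int
) -> AxisRotation:
    a, b = _TRANSVERSE[axis]
    term_ab = np.einsum("fi,fi->f", pos[a], vel[b])  # per-frame sums
    term_ba = np.einsum("fi,fi->f", pos[b], vel[a])
    moment = np.einsum("fi,fi->f", pos[a], pos[a]) + np.einsum("fi,fi->f", pos[b], pos[b])
    L = term_ab - term_ba
    mean_moment = float(moment.mean())
    omega = float(L.mean() / mean_moment)

    n_blocks = min(n_blocks, len(L))
    blocks = np.array_split(np.arange(len(L)), n_blocks)
    omega_blocks = np.array([L[idx].mean() / moment[idx].mean() for idx in blocks])
    omega_err = (
        float(omega_blocks.std(ddof=1) / np.sqrt(n_blocks)) if n_blocks > 1 else np.nan
    )
    return AxisRotation(
        axis=axis,
        term_ab=float(term_ab.mean()),
        term_ba=float(term_ba.mean()),
        L=float(L.mean()),
        moment=mean_moment,
        omega=omega,
        term_ab_err=block_error(term_ab, n_blocks),
        term_ba_err=block_error(term_ba, n_blocks),
        L_err=block_error(L, n_blocks),
        omega_err=omega_err,
    )


def rotation_diagnostics(trajectory: Trajectory, n_blocks: int = 20) -> RotationDiagnostics:
    """Angular-momentum rotation estimate about each axis.

    Positions and single-step displacements are both taken relative to the
    chain center of mass; velocities are displacement / dt at the sampled
    step.  Raises ``ValueError`` when the trajectory has no displacement
    channel.
    """
    pos3 = trajectory.centered_positions()
    vel3 = trajectory.centered_displacements() / trajectory.config.time_step
    # contiguous per-component arrays keep the per-frame reductions in cache
    pos = [np.ascontiguousarray(pos3[:, :, k]) for k in range(3)]
    vel = [np.ascontiguousarray(vel3[:, :, k]) for k in range(3)]
    del pos3, vel3
    return RotationDiagnostics(
        **{ax: _axis_rotation(ax, pos, vel, n_blocks) for ax in ("x", "y", "z")}
    )


def end_to_end_correlations(
    trajectory: Trajectory, max_lag: int
) -> tuple[CorrelationFunction, CorrelationFunction]:
    """Autocorrelations <Re(0).Re(t)> of the end-to-end vector and its unit vector.

    Raw (non-mean-subtracted) dot-product correlators, so the unit-vector
    function starts at exactly 1.  Frames where the end-to-end vector has
    zero length are excluded as origins of the unit-vector estimate.
    """
    if trajectory.n_frames < 2:
        raise ValueError("need at least two frames")
    re = trajectory.positions[:, -1, :] - trajectory.positions[:, 0, :]
    spacing = trajectory.frame_spacing

    vec = _vector_autocorrelation(re, max_lag, spacing, ("Re", "Re"))

    norms = np.linalg.norm(re, axis=1)
    valid = norms > 0
    unit = np.zeros_like(re)
    unit[valid] = re[valid] / norms[valid, None]
    if valid.all():
        uni = _vector_autocorrelation(unit, max_lag, spacing, ("Re_hat", "Re_hat"))
    else:  # rare degenerate frames: slow masked estimator
        uni = _masked_vector_autocorrelation(unit, valid, max_lag, spacing)
    return vec, uni


def _vector_autocorrelation(v, max_lag, spacing, labels) -> CorrelationFunction:
    parts = [correlate(v[:, a], v[:, a], max_lag, subtract_mean=False) for a in range(3)]
    values = sum(p.values for p in parts)
    return CorrelationFunction(
        lags=parts[0].lags * spacing,
        values=values,
        n_samples=parts[0].n_samples,
        labels=labels,
    )


def _masked_vector_autocorrelation(v, valid, max_lag, spacing) -> CorrelationFunction:
    n = len(v)
    values = np.empty(max_lag + 1)
    counts = np.empty(max_lag + 1, dtype=int)
    for lag in range(max_lag + 1):
        ok = valid[: n - lag] & valid[lag:]
        counts[lag] = ok.sum()
        dots = np.einsum("ij,ij->i", v[: n - lag][ok], v[lag:][ok])
        values[lag] = dots.mean() if counts[lag] else np.nan
    return CorrelationFunction(
        lags=np.arange(max_lag + 1) * spacing,
        values=values,
        n_samples=counts,
        labels=("Re_hat", "Re_hat"),
    )


def com_msd(trajectory: Trajectory, max_lag: int = 20) -> tuple[np.ndarray, np.ndarray, float]:
    """Center-of-mass mean-square displacement and its through-origin slope.

    The COM decouples from the springs and (with COM-referenced shear)
    from the flow, so it diffuses freely: MSD(t) = 6 kBT t / (N f) in 3D.
    Returns (lag times, MSD values, fitted slope); the slope fit is least
    squares through the origin over lags 1..max_lag frames, in lab-frame
    coordinates.
    """
    com = trajectory.com()
    if trajectory.n_frames <= max_lag:
        raise ValueError("trajectory shorter than requested maximum lag")
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(max_lag)
    for j, lag in enumerate(lags):
        d = com[lag:] - com[:-lag]
        msd[j] = np.mean((d**2).sum(axis=1))
    t = lags * trajectory.frame_spacing
    slope = float((msd * t).sum() / (t * t).sum())
    return t, msd, slope


def _distance_samples(trajectory: Trajectory):
    """Yield (category, list-of-arrays) of sampled distances."""
    pos = trajectory.positions
    n = trajectory.n_beads

    def sep(i, j):
        return np.linalg.norm(pos[:, j, :] - pos[:, i, :], axis=1)

    yield "nearest_neighbor", [sep(i, i + 1) for i in range(n - 1)]
    yield "second_nearest_neighbor", [sep(i, i + 2) for i in range(n - 2)]
    yield "end_to_end", [sep(0, n - 1)]
    com = trajectory.centered_positions()
    yield "bead_to_com", [np.linalg.norm(com[:, i, :], axis=1) for i in range(n)]
    yield "all_pairs", [sep(i, j) for i in range(n - 1) for j in range(i + 1, n)]


def distance_distributions(
    trajectory: Trajectory, n_bins: int = 100, bin_width: float | None = None
) -> DistanceDistributions:
    """Histograms of the chain's characteristic distances, over all frames.

    Default binning: ``n_bins`` uniform bins from 0 to 1.05x the largest
    observed distance in each category; ``bin_width`` (if given) fixes the
    width instead.
    """
    if trajectory.n_frames < 1:
        raise ValueError("need at least one frame")
    if bin_width is not None and bin_width <= 0:
        raise ValueError(f"bin width must be positive, got {bin_width}")
    out = {}
    for name, arrays in _distance_samples(trajectory):
        top = max((float(a.max()) for a in arrays if a.size), default=0.0)
        top = 1.05 * top if top > 0 else 1.0
        if bin_width is not None:
            edges = np.arange(0.0, top + bin_width, bin_width)
        else:
            edges = np.linspace(0.0, top, n_bins + 1)
        counts = np.zeros(len(edges) - 1, dtype=int)
        for a in arrays:
            counts += np.histogram(a, bins=edges)[0]
        out[name] = Histogram(edges, counts)
    return DistanceDistributions(**out)
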