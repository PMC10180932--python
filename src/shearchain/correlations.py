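"""Stationary correlation estimation, early-time exponential fits, and the
shear-sweep driver.

In the unsheared free-draining chain the mode correlators obey

    <C_n,a(0) C_m,b(t)> = delta_nm delta_ab <C_n,a(0)^2> exp(-Gamma_n t),

so any cross-correlation (different mode index or different axis) is a
null channel.  Under shear this factorization breaks: the x amplitudes
and rates become G-dependent and the (n,x)-(n,y) channels acquire
equal-time correlations.  ``run_sweep`` measures all of this across a
set of shear rates, with block-averaging errors throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.fft

from .config import SimulationConfig

__all__ = [
    "CorrelationFunction",
    "ExponentialFit",
    "SweepSummary",
    "correlate",
    "fit_initial_exponential",
    "block_error",
    "run_sweep",
]


class FitError(ValueError):
    """Raised when an exponential fit window contains too few usable points."""


@dataclass(frozen=True)
class CorrelationFunction:
    """A stationary auto- or cross-correlation estimate on a uniform lag grid.

    ``values[j] = < a(t) b(t + lags[j]) >`` averaged over all admissible
    origins; ``n_samples[j]`` is the number of origins that entered lag j.
    """

    lags: np.ndarray
    values: np.ndarray
    n_samples: np.ndarray
    labels: tuple = ("a", "b")
    fit: "ExponentialFit | None" = None

    def with_fit(self, fit: "ExponentialFit") -> "CorrelationFunction":
        return CorrelationFunction(self.lags, self.values, self.n_samples, self.labels, fit)


@dataclass(frozen=True)
class ExponentialFit:
    """Result of a log-linear early-time fit A exp(-rate * t).

    ``window`` is the number of leading lag points used; ``crossed`` says
    whether the correlator actually fell below 1/e of its initial value
    inside the available lags (if not, the fitted rate is unreliable);
    ``log_rms_residual`` is the rms residual of the fit in log space.
    """

    amplitude: float
    rate: float
    window: int
    crossed: bool
    log_rms_residual: float


def block_error(series: np.ndarray, n_blocks: int = 20) -> float:
    """Standard error of the mean of a correlated series via block averaging.

    The series is cut into ``n_blocks`` contiguous blocks; the error is the
    standard deviation of the block means over sqrt(n_blocks).  Valid when
    blocks are longer than the series' correlation time.
    """
    series = np.asarray(series)
    n_blocks = min(n_blocks, len(series))
    if n_blocks < 2:
        return float("nan")
    means = np.array([b.mean() for b in np.array_split(series, n_blocks)])
    return float(means.std(ddof=1) / np.sqrt(n_blocks))


def correlate(
    a: np.ndarray,
    b: np.ndarray | None = None,
    max_lag: int | None = None,
    spacing: float = 1.0,
    subtract_mean: bool = True,
    labels: tuple = ("a", "b"),
) -> CorrelationFunction:
    """Time-averaged stationary correlation <a(t) b(t+tau)>, FFT-accelerated.

    Sample means are subtracted by default (the stationary-fluctuation
    convention), so the lag-0 value of an autocorrelation is the sample
    variance.  ``b=None`` or ``b is a`` gives the autocorrelation.
    """
    a = np.asarray(a, dtype=float)
    auto = b is None or b is a
    b = a if auto else np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"series must be equal-length 1-D, got {a.shape} and {b.shape}")
    n = len(a)
    if max_lag is None:
        max_lag = n - 1
    if not 0 <= max_lag < n:
        raise ValueError(f"max_lag must be in [0, {n - 1}], got {max_lag}")
    if subtract_mean:
        a = a - a.mean()
        b = b if auto else b - b.mean()
        if auto:
            b = a
    nfft = scipy.fft.next_fast_len(n + max_lag + 1, real=True)
    fa = scipy.fft.rfft(a, nfft)
    fb = fa if auto and subtract_mean else scipy.fft.rfft(b, nfft)
    raw = scipy.fft.irfft(np.conj(fa) * fb, nfft)[: max_lag + 1]
    counts = n - np.arange(max_lag + 1)
    return CorrelationFunction(
        lags=spacing * np.arange(max_lag + 1),
        values=raw / counts,
        n_samples=counts,
        labels=labels,
    )


def fit_initial_exponential(cf: CorrelationFunction, min_points: int = 3) -> ExponentialFit:
    """Fit the early-time segment of a correlator to a single exponential.

    The fit window runs from lag 0 up to (excluding) the first lag at
    which the estimate drops below 1/e of its lag-0 value, truncated at
    the first non-positive estimate; unweighted least squares on
    log(values).  Raises ``FitError`` if fewer than ``min_points`` lags
    remain.
    """
    v = np.asarray(cf.values, dtype=float)
    if len(v) == 0 or v[0] <= 0:
        raise FitError("correlation must be positive at lag 0")
    below = np.nonzero(v < v[0] / np.e)[0]
    end = int(below[0]) if below.size else len(v)
    nonpos = np.nonzero(v[:end] <= 0)[0]
    if nonpos.size:
        end = int(nonpos[0])
    if end < min_points:
        raise FitError(f"only {end} usable points in the early-time window (< {min_points})")
    t, y = cf.lags[:end], np.log(v[:end])
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    return ExponentialFit(
        amplitude=float(np.exp(intercept)),
        rate=float(-slope),
        window=end,
        crossed=bool(below.size),
        log_rms_residual=float(np.sqrt(np.mean(resid**2))),
    )


@dataclass(frozen=True)
class SweepSummary:
    """Aggregated diagnostics across a set of shear rates.

    modes
        One row per (G, n, axis): fitted rate, its block error, the mode's
        sample variance (the correlator's equal-time amplitude) and error.
    cross
        One row per (G, n, m, axis_a, axis_b): equal-time cross amplitude
        <C_{n,a} C_{m,b}> with block error (means subtracted).
    rotation
        One row per (G, rotation axis): estimator terms, L, moment, omega
        and block errors.
    shape
        One row per G: second moments <x_a x_b> with block errors, rg2.
    xy_cross_functions
        (G, n) -> full <C_ny(0) C_nx(t)> correlation function for the
        low-n channels, for lag-shape inspection (this direction carries
        the rise-then-fall signature of the shear coupling).
    """

    modes: pd.DataFrame
    cross: pd.DataFrame
    rotation: pd.DataFrame
    shape: pd.DataFrame
    xy_cross_functions: dict
    seeds: dict
    base_config: SimulationConfig

    def to_csv(self, path) -> None:
        self.modes.to_csv(path, index=False)


_AX = {"x": 0, "y": 1, "z": 2}


def _blockwise_rate_error(series_a, series_b, max_lag, spacing, n_blocks):
    """Std error of the fitted rate from independent fits on contiguous blocks."""
    n = len(series_a)
    if n // n_blocks <= max_lag:
        return float("nan")
    rates = []
    for idx in np.array_split(np.arange(n), n_blocks):
        cf = correlate(series_a[idx], series_b[idx], max_lag, spacing)
        try:
            rates.append(fit_initial_exponential(cf).rate)
        except FitError:
            continue
    if len(rates) < 2:
        return float("nan")
    rates = np.array(rates)
    return float(rates.std(ddof=1) / np.sqrt(len(rates)))


def analyze_modes(
    mode_series: np.ndarray,
    spacing: float,
    n_modes: int,
    max_lag: int,
    n_blocks: int = 20,
    cross_mode_pairs: Sequence[tuple[int, int]] = ((1, 2), (1, 3), (2, 3)),
) -> tuple[list[dict], list[dict], dict]:
    """Fit autocorrelations and measure cross amplitudes for one run.

    ``mode_series`` is the (F, N, 3) Rouse amplitude series.  Returns
    (auto rows, cross rows, xy cross-correlation functions keyed by n).
    """
    auto_rows, cross_rows = [], []
    xy_functions = {}
    for n in range(1, n_modes + 1):
        for ax in ("x", "y", "z"):
            s = mode_series[:, n, _AX[ax]]
            cf = correlate(s, None, max_lag, spacing, labels=(f"C{n}{ax}", f"C{n}{ax}"))
            fit = fit_initial_exponential(cf)
            var_blocks = np.array(
                [b.var() for b in np.array_split(s - s.mean(), n_blocks)]
            )
            auto_rows.append(
                {
                    "n": n,
                    "axis": ax,
                    "rate": fit.rate,
                    "rate_err": _blockwise_rate_error(s, s, max_lag, spacing, n_blocks),
                    "amplitude": float(s.var()),
                    "amplitude_err": float(var_blocks.std(ddof=1) / np.sqrt(n_blocks)),
                    "crossed": fit.crossed,
                }
            )
        # same-n, different-axis equal-time amplitudes
        for ax_a, ax_b in (("x", "y"), ("y", "z"), ("z", "x")):
            sa = mode_series[:, n, _AX[ax_a]]
            sb = mode_series[:, n, _AX[ax_b]]
            prod = (sa - sa.mean()) * (sb - sb.mean())
            cross_rows.append(
                {
                    "n": n,
                    "m": n,
                    "axis_a": ax_a,
                    "axis_b": ax_b,
                    "amplitude": float(prod.mean()),
                    "error": block_error(prod, n_blocks),
                }
            )
        if n <= 3:
            # <C_ny(0) C_nx(t)>: the shear term G*C_ny in the x-mode equation
            # pumps gradient-direction amplitude into the flow direction, so
            # this cross-correlation first rises and then decays; the reversed
            # direction is a plain exponential.
            xy_functions[n] = correlate(
                mode_series[:, n, 1], mode_series[:, n, 0], max_lag, spacing,
                labels=(f"C{n}y", f"C{n}x"),
            )
    # differing-mode null channels
    for n, m in cross_mode_pairs:
        for ax_a, ax_b in (("x", "x"), ("x", "y"), ("y", "y")):
            sa = mode_series[:, n, _AX[ax_a]]
            sb = mode_series[:, m, _AX[ax_b]]
            prod = (sa - sa.mean()) * (sb - sb.mean())
            cross_rows.append(
                {
                    "n": n,
                    "m": m,
                    "axis_a": ax_a,
                    "axis_b": ax_b,
                    "amplitude": float(prod.mean()),
                    "error": block_error(prod, n_blocks),
                }
            )
    return auto_rows, cross_rows, xy_functions


def _segmented_rotation(config, n_segments: int, segment_steps: int):
    """Rotation statistics from contiguous every-step-sampled segments.

    The angular-momentum estimator's noise comes from the thermal part of
    the single-step displacements and is white between sampled steps, so
    its error scales with the number of *sampled* steps: sampling every
    step (stride 1) extracts all of it.  Segments continue one physical
    run (each starts from the previous end state, fresh noise stream) and
    are long enough to be independent, so segment-to-segment scatter gives
    the standard errors; omega errors come from per-segment ratios.
    """
    from .observables import AxisRotation, RotationDiagnostics, rotation_diagnostics
    from .simulator import simulate

    per_axis: dict[str, list] = {"x": [], "y": [], "z": []}
    positions = None
    for j in range(n_segments):
        seg_config = config.replace(
            sample_stride=1,
            n_production_steps=segment_steps,
            n_thermalization_steps=config.n_thermalization_steps if j == 0 else 0,
            seed=(config.seed + 10_007 * (j + 1)) % 2**31,
        )
        traj = simulate(seg_config, initial=positions)
        positions = traj.positions[-1]
        rot = rotation_diagnostics(traj, n_blocks=2)
        for ax in ("x", "y", "z"):
            r = rot[ax]
            per_axis[ax].append((r.term_ab, r.term_ba, r.L, r.moment, r.omega))

    out = {}
    root = np.sqrt(n_segments)
    for ax, rows in per_axis.items():
        arr = np.array(rows)
        mean = arr.mean(axis=0)
        err = arr.std(axis=0, ddof=1) / root
        out[ax] = AxisRotation(
            axis=ax,
            term_ab=mean[0],
            term_ba=mean[1],
            L=mean[2],
            moment=mean[3],
            omega=mean[2] / mean[3],
            term_ab_err=err[0],
            term_ba_err=err[1],
            L_err=err[2],
            omega_err=err[4],
        )
    return RotationDiagnostics(**out)


def run_sweep(
    base_config: SimulationConfig,
    shear_values: Iterable[float],
    n_modes: int = 7,
    max_lag_time: float = 40.0,
    n_blocks: int = 20,
    rotation_segments: int = 20,
    rotation_segment_steps: int | None = None,
) -> SweepSummary:
    """Simulate at each shear rate and aggregate all diagnostics.

    Each G gets its own seed, derived deterministically from the base
    seed (base + index).  ``max_lag_time`` bounds the correlation lags in
    time units; fits use the early-time window rule.

    If ``rotation_segment_steps`` is given, rotation diagnostics come from
    a dedicated set of ``rotation_segments`` contiguous, every-step-sampled
    runs of that many steps each (see :func:`_segmented_rotation`) instead
    of the stride-sampled mode trajectory, which wastes most of the
    angular-momentum information.
    """
    from .observables import rotation_diagnostics, shape_moments
    from .rouse import mode_trajectory
    from .simulator import simulate

    shear_values = list(shear_values)
    if len(shear_values) < 2:
        raise ValueError("a sweep needs at least 2 shear values")
    if len(set(shear_values)) != len(shear_values):
        raise ValueError("shear values must be distinct")
    n_modes = min(n_modes, base_config.n_beads - 1)

    mode_rows, cross_rows, rot_rows, shape_rows = [], [], [], []
    xy_functions, seeds = {}, {}
    for idx, g in enumerate(shear_values):
        config = base_config.replace(shear_rate=g, seed=base_config.seed + idx)
        seeds[g] = config.seed
        try:
            traj = simulate(config)
            spacing = traj.frame_spacing
            max_lag = min(int(round(max_lag_time / spacing)), traj.n_frames - 1)
            modes = mode_trajectory(traj)
            auto, cross, xyf = analyze_modes(modes, spacing, n_modes, max_lag, n_blocks)
            shape = shape_moments(traj, n_blocks)
            if rotation_segment_steps:
                del modes, traj  # free the mode run before the segment runs
                rot = _segmented_rotation(config, rotation_segments, rotation_segment_steps)
            else:
                rot = rotation_diagnostics(traj, n_blocks)
        except Exception as exc:
            raise RuntimeError(f"sweep failed at G={g}") from exc
        for row in auto + cross:
            row["G"] = g
        mode_rows.extend(auto)
        cross_rows.extend(cross)
        for ax in ("x", "y", "z"):
            r = rot[ax]
            rot_rows.append(
                {
                    "G": g,
                    "axis": ax,
                    "term_ab": r.term_ab,
                    "term_ab_err": r.term_ab_err,
                    "term_ba": r.term_ba,
                    "term_ba_err": r.term_ba_err,
                    "L": r.L,
                    "L_err": r.L_err,
                    "moment": r.moment,
                    "omega": r.omega,
                    "omega_err": r.omega_err,
                }
            )
        srow = {"G": g, "rg2": shape.rg2}
        for a, la in enumerate("xyz"):
            for b, lb in enumerate("xyz"):
                if a <= b:
                    srow[f"{la}{lb}"] = shape.second[a, b]
                    srow[f"{la}{lb}_err"] = shape.second_err[a, b]
        shape_rows.append(srow)
        for n, cf in xyf.items():
            xy_functions[(g, n)] = cf

    cols = ["G", "n", "axis", "rate", "rate_err", "amplitude", "amplitude_err", "crossed"]
    ccols = ["G", "n", "m", "axis_a", "axis_b", "amplitude", "error"]
    return SweepSummary(
        modes=pd.DataFrame(mode_rows)[cols],
        cross=pd.DataFrame(cross_rows)[ccols],
        rotation=pd.DataFrame(rot_rows),
        shape=pd.DataFrame(shape_rows),
        xy_cross_functions=xy_functions,
        seeds=seeds,
        base_config=base_config,
    )
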