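"""Multi-frame XYZ export/import of trajectories.

Each frame is the standard XYZ block: bead count, a comment line, then
one ``C x y z`` line per bead.  The comment line carries the frame time,
the integration step and the config digest so a trajectory round-trips
with enough metadata for the diagnostics:

    t=0.01 dt=0.001 stride=10 digest=0123456789ab

Single-step displacements, when present, are written to a companion file
in the same layout (displacement components in place of coordinates).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .config import SimulationConfig
from .simulator import Trajectory

__all__ = ["write_xyz", "read_xyz"]

_COMMENT_RE = re.compile(r"t=(?P<t>[^ ]+) dt=(?P<dt>[^ ]+) stride=(?P<stride>\d+)")


def _write_frames(path: Path, frames: np.ndarray, times, config: SimulationConfig) -> None:
    digest = config.digest()
    with open(path, "w") as fh:
        for frame, t in zip(frames, times):
            fh.write(f"{frame.shape[0]}\n")
            fh.write(
                f"t={t:.12g} dt={config.time_step:.12g} "
                f"stride={config.sample_stride} digest={digest}\n"
            )
            for row in frame:
                fh.write(f"C {row[0]:.12g} {row[1]:.12g} {row[2]:.12g}\n")


def write_xyz(
    trajectory: Trajectory, path: str | Path, displacement_path: str | Path | None = None
) -> None:
    """Write a trajectory (and optionally its displacement channel) as XYZ."""
    _write_frames(Path(path), trajectory.positions, trajectory.times, trajectory.config)
    if displacement_path is not None:
        if trajectory.displacements is None:
            raise ValueError("trajectory has no displacement channel to write")
        _write_frames(
            Path(displacement_path),
            trajectory.displacements,
            trajectory.times,
            trajectory.config,
        )


def _read_frames(path: Path):
    frames, times, meta = [], [], None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        match = _COMMENT_RE.search(lines[i + 1])
        if match is None:
            raise ValueError(f"{path}: frame comment line lacks t=/dt=/stride= metadata")
        times.append(float(match["t"]))
        meta = (float(match["dt"]), int(match["stride"]))
        frame = np.array(
            [[float(v) for v in lines[i + 2 + j].split()[1:4]] for j in range(n)]
        )
        frames.append(frame)
        i += 2 + n
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return np.array(frames), np.array(times), meta


def read_xyz(
    path: str | Path,
    displacement_path: str | Path | None = None,
    config: SimulationConfig | None = None,
) -> Trajectory:
    """Read a trajectory written by :func:`write_xyz`.

    If no config is supplied, a minimal one is reconstructed from the
    frame metadata (bead count, time step, stride); physical parameters
    not stored in the XYZ file keep their defaults.
    """
    positions, times, (dt, stride) = _read_frames(Path(path))
    displacements = None
    if displacement_path is not None:
        displacements, dtimes, _ = _read_frames(Path(displacement_path))
        if displacements.shape != positions.shape or not np.allclose(dtimes, times):
            raise ValueError("displacement file does not match the trajectory file")
    if config is None:
        config = SimulationConfig(
            n_beads=positions.shape[1],
            time_step=dt,
            sample_stride=stride,
            n_production_steps=len(positions) * stride,
            n_thermalization_steps=0,
        )
    return Trajectory(positions, times, config, displacements)
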