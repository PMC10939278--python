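"""Trajectory CSV round-tripping.

CSV with header ``t,T,C,D,IL2,Z``, one row per node, full double precision
(17 significant digits, so write/read round-trips are exact).  CSV is the
only trajectory format, keeping outputs diffable.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .solver import Trajectory

__all__ = ["TRAJECTORY_HEADER", "read_trajectory", "write_trajectory"]

TRAJECTORY_HEADER = ["t", "T", "C", "D", "IL2", "Z"]


class TrajectoryParseError(ValueError):
    """Malformed trajectory file (bad header, ragged or non-numeric rows)."""


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRAJECTORY_HEADER)
        for t, row in zip(traj.times, traj.states):
            writer.writerow([f"{t:.17g}"] + [f"{x:.17g}" for x in row])
    return path


def read_trajectory(path: str | Path) -> Trajectory:
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise TrajectoryParseError(f"{path}: empty file") from None
        if [h.strip() for h in header] != TRAJECTORY_HEADER:
            raise TrajectoryParseError(
                f"{path}: expected header {','.join(TRAJECTORY_HEADER)!r}, "
                f"got {','.join(header)!r}"
            )
        times, states = [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 6:
                raise TrajectoryParseError(
                    f"{path}: line {lineno}: expected 6 fields, got {len(row)}"
                )
            try:
                values = [float(x) for x in row]
            except ValueError as exc:
                raise TrajectoryParseError(f"{path}: line {lineno}: {exc}") from None
            times.append(values[0])
            states.append(values[1:])
    if not times:
        raise TrajectoryParseError(f"{path}: no data rows")
    return Trajectory(np.array(times), np.array(states))
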