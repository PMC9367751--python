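"""Text-format writers and readers: extended XYZ trajectories, CSV tables,
JSON run metadata, template site tables.

The extended-XYZ record carries, per monomer: species label, centre position,
orientation quaternion (scalar first) and dipole vector, one frame per
snapshot.  Observable tables are CSV with ``#``-prefixed header metadata so
they remain self-describing after aggregation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_xyz",
    "read_xyz",
    "write_table",
    "read_table",
    "write_metadata",
    "write_template",
]

_XYZ_COLUMNS = "species:S:1:pos:R:3:quat:R:4:dipole:R:3"


def write_xyz(path, trajectory, species: str = "M") -> None:
    """Write a Trajectory (or (n,L,3) positions) as extended XYZ."""
    pos = trajectory.positions if hasattr(trajectory, "positions") else np.asarray(trajectory)
    if pos.ndim == 2:
        pos = pos[None]
    n_frames, n = pos.shape[:2]
    quat = getattr(trajectory, "orientations", None)
    mu = getattr(trajectory, "dipoles", None)
    if quat is None:
        quat = np.tile([1.0, 0.0, 0.0, 0.0], (n_frames, n, 1))
    if mu is None:
        mu = np.zeros((n_frames, n, 3))
    with open(path, "w") as fh:
        for f in range(n_frames):
            fh.write(f"{n}\n")
            fh.write(f'Properties={_XYZ_COLUMNS} Frame={f}\n')
            for i in range(n):
                x, y, z = pos[f, i]
                qw, qx, qy, qz = quat[f, i]
                mx, my, mz = mu[f, i]
                fh.write(
                    f"{species} {x:.10g} {y:.10g} {z:.10g} "
                    f"{qw:.10g} {qx:.10g} {qy:.10g} {qz:.10g} "
                    f"{mx:.10g} {my:.10g} {mz:.10g}\n"
                )


def read_xyz(path):
    """Read an extended-XYZ trajectory back into (positions, quats, dipoles)."""
    pos_frames, quat_frames, mu_frames = [], [], []
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        n = int(lines[k].strip())
        body = lines[k + 2: k + 2 + n]
        vals = np.array([ln.split()[1:] for ln in body], dtype=float)
        pos_frames.append(vals[:, 0:3])
        quat_frames.append(vals[:, 3:7])
        mu_frames.append(vals[:, 7:10])
        k += 2 + n
    return (np.array(pos_frames), np.array(quat_frames), np.array(mu_frames))


def write_table(path, table: pd.DataFrame, metadata: dict | None = None) -> None:
    """CSV with '#'-prefixed JSON metadata header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if metadata:
            fh.write("# " + json.dumps(metadata, default=str) + "\n")
        table.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_metadata(path, metadata: dict) -> None:
    """JSON sidecar with every parameter and seed of a run."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(metadata, fh, indent=2, default=str)


def write_template(path, template) -> None:
    """Site table (id, role, x, y, z, sigma, epsilon) as CSV."""
    from .geometry import template_table

    template_table(template).to_csv(path, index=False)
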