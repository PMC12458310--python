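"""Trajectory and table serialization.

The primary trajectory format is extended XYZ (one block per frame) so that
standard molecular viewers open the output directly: the species column
encodes the bead role (M membrane, N nucleus, A actin, H actin head), the z
column is 0, and the comment line carries ``key=value`` pairs with the frame
time, the energy breakdown and provenance (config hash, seed, package
version).  A flat CSV alternative (frame, bead, role, filament_id, x, y) is
also supported.  Positions are printed with 12 significant digits, so a
write/read round trip reproduces them to better than 1e-9.
"""
from __future__ import annotations

import hashlib
import json
import pathlib

import numpy as np
import pandas as pd

from .cell_builder import ROLE_SYMBOL, SYMBOL_ROLE, Configuration, Role
from .config import SimulationConfig
from .dynamics import Trajectory
from .mechanics import EnergyBreakdown

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "config_hash",
    "provenance_comments",
    "write_table",
]

_ENERGY_KEYS = ("stretch", "bend", "attraction", "repulsion", "area")


def config_hash(config: SimulationConfig | None) -> str:
    """Short stable hash of a config (12 hex chars)."""
    if config is None:
        return "unknown"
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_comments(config: SimulationConfig | None) -> list[str]:
    from . import __version__

    seed = config.seed if config is not None else "unknown"
    return [
        f"# config_hash={config_hash(config)}",
        f"# seed={seed}",
        f"# neuritesim_version={__version__}",
    ]


def _frame_comment(
    frame: Configuration, energy: EnergyBreakdown | None, config: SimulationConfig | None
) -> str:
    from . import __version__

    parts = [
        "Properties=species:S:1:pos:R:3:filament_id:I:1",
        f"time={frame.time:.12g}",
    ]
    if energy is not None:
        for key in _ENERGY_KEYS:
            parts.append(f"{key}={getattr(energy, key):.12g}")
        parts.append(f"total={energy.total:.12g}")
    parts.append(f"config_hash={config_hash(config)}")
    if config is not None:
        parts.append(f"seed={config.seed}")
    parts.append(f"version={__version__}")
    return " ".join(parts)


def write_trajectory(
    trajectory: Trajectory, path: str | pathlib.Path, format: str | None = None
) -> None:
    """Write all frames to ``path`` in extended-XYZ or flat-CSV format."""
    path = pathlib.Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "xyz")
    if fmt == "xyz":
        _write_xyz(trajectory, path)
    elif fmt == "csv":
        _write_csv(trajectory, path)
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")


def _write_xyz(trajectory: Trajectory, path: pathlib.Path) -> None:
    energies = trajectory.energies or [None] * len(trajectory.frames)
    with open(path, "w") as fh:
        for frame, energy in zip(trajectory.frames, energies):
            fh.write(f"{frame.n_beads}\n")
            fh.write(_frame_comment(frame, energy, trajectory.config) + "\n")
            for i in range(frame.n_beads):
                sym = ROLE_SYMBOL[Role(int(frame.role[i]))]
                x, y = frame.positions[i]
                fh.write(f"{sym} {x:.12g} {y:.12g} 0 {int(frame.filament_id[i])}\n")


def _write_csv(trajectory: Trajectory, path: pathlib.Path) -> None:
    rows = []
    for fi, frame in enumerate(trajectory.frames):
        for b in range(frame.n_beads):
            rows.append(
                (
                    fi,
                    b,
                    ROLE_SYMBOL[Role(int(frame.role[b]))],
                    int(frame.filament_id[b]),
                    frame.positions[b, 0],
                    frame.positions[b, 1],
                    frame.time,
                )
            )
    table = pd.DataFrame(
        rows, columns=["frame", "bead", "role", "filament_id", "x", "y", "time"]
    )
    write_table(table, path, trajectory.config, float_format="%.12g")


def _parse_kv(comment: str) -> dict[str, str]:
    out = {}
    for token in comment.split():
        if "=" in token:
            key, _, value = token.partition("=")
            out[key] = value
    return out


def read_trajectory(path: str | pathlib.Path, format: str | None = None) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`.

    The returned Trajectory has ``config=None``; malformed files raise
    ValueError naming the offending line.
    """
    path = pathlib.Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "xyz")
    if fmt == "csv":
        return _read_csv(path)
    return _read_xyz(path)


def _read_xyz(path: pathlib.Path) -> Trajectory:
    frames: list[Configuration] = []
    energies: list[EnergyBreakdown] = []
    lines = pathlib.Path(path).read_text().splitlines()
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            n = int(lines[ln].strip())
        except ValueError:
            raise ValueError(f"{path}:{ln + 1}: expected bead count, got {lines[ln]!r}")
        if ln + 1 + n >= len(lines) + 1 and n > 0:
            raise ValueError(f"{path}:{ln + 1}: truncated frame (expected {n} beads)")
        meta = _parse_kv(lines[ln + 1])
        time = float(meta.get("time", 0.0))
        positions = np.empty((n, 2))
        role = np.empty(n, dtype=np.int8)
        filament_id = np.full(n, -1, dtype=np.int32)
        for b in range(n):
            lineno = ln + 2 + b
            if lineno >= len(lines):
                raise ValueError(f"{path}:{lineno + 1}: truncated frame")
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise ValueError(
                    f"{path}:{lineno + 1}: expected 'species x y z [filament_id]', "
                    f"got {lines[lineno]!r}"
                )
            sym = parts[0]
            if sym not in SYMBOL_ROLE:
                raise ValueError(f"{path}:{lineno + 1}: unknown species {sym!r}")
            role[b] = int(SYMBOL_ROLE[sym])
            try:
                positions[b, 0] = float(parts[1])
                positions[b, 1] = float(parts[2])
                if len(parts) >= 5:
                    filament_id[b] = int(parts[4])
            except ValueError:
                raise ValueError(f"{path}:{lineno + 1}: malformed record {lines[lineno]!r}")
        frames.append(
            Configuration(
                positions=positions,
                velocities=np.zeros_like(positions),
                role=role,
                filament_id=filament_id,
                time=time,
            )
        )
        if all(k in meta for k in _ENERGY_KEYS):
            energies.append(EnergyBreakdown(*(float(meta[k]) for k in _ENERGY_KEYS)))
        ln += 2 + n
    if not frames:
        raise ValueError(f"{path}: no frames found")
    if energies and len(energies) != len(frames):
        energies = []
    return Trajectory(frames=frames, energies=energies, config=None)


def _read_csv(path: pathlib.Path) -> Trajectory:
    table = pd.read_csv(path, comment="#")
    required = {"frame", "bead", "role", "filament_id", "x", "y"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    frames = []
    for fi, grp in table.groupby("frame", sort=True):
        grp = grp.sort_values("bead")
        positions = grp[["x", "y"]].to_numpy(dtype=float)
        role = np.array([int(SYMBOL_ROLE[s]) for s in grp["role"]], dtype=np.int8)
        frames.append(
            Configuration(
                positions=positions,
                velocities=np.zeros_like(positions),
                role=role,
                filament_id=grp["filament_id"].to_numpy(dtype=np.int32),
                time=float(grp["time"].iloc[0]) if "time" in grp else float(fi),
            )
        )
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return Trajectory(frames=frames, energies=[], config=None)


def write_table(
    table: pd.DataFrame,
    path: str | pathlib.Path,
    config: SimulationConfig | None = None,
    float_format: str = "%.9g",
) -> None:
    """Write a DataFrame as CSV with a provenance comment header."""
    path = pathlib.Path(path)
    with open(path, "w") as fh:
        for line in provenance_comments(config):
            fh.write(line + "\n")
        table.to_csv(fh, index=False, float_format=float_format)


def write_energy_series(trajectory: Trajectory, path: str | pathlib.Path) -> None:
    """Per-frame energy breakdown CSV (time + one column per term)."""
    rows = [
        {"time": f.time, **e.as_dict()}
        for f, e in zip(trajectory.frames, trajectory.energies)
    ]
    write_table(pd.DataFrame(rows), path, trajectory.config)
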