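"""Deterministic contour rendering of simulated cell morphologies.

The membrane and nuclear rings are drawn as closed polylines, filaments as
open polylines, and actin heads as markers, on equal-aspect axes.  SVG output
is byte-reproducible: the hash salt is pinned and the date metadata dropped.
"""
from __future__ import annotations

import pathlib

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cell_builder import Configuration, Role

__all__ = ["render_contour"]

_STYLE = {
    "membrane": {"color": "#1f77b4", "lw": 1.5},
    "nucleus": {"color": "#7f7f7f", "lw": 1.2},
    "filament": {"color": "#2ca02c", "lw": 0.8},
    "head": {"color": "#d62728", "s": 12.0},
}


def render_contour(frame: Configuration, path: str | pathlib.Path) -> None:
    """Render one frame to ``path`` (SVG by extension, else PNG)."""
    path = pathlib.Path(path)
    with plt.rc_context({"svg.hashsalt": "neuritesim"}):
        fig, ax = plt.subplots(figsize=(5, 5))
        try:
            mem = frame.positions[frame.role == int(Role.MEMBRANE)]
            if len(mem):
                ring = np.vstack([mem, mem[:1]])
                ax.plot(ring[:, 0], ring[:, 1], **_STYLE["membrane"])
            nuc = frame.positions[frame.role == int(Role.NUCLEUS)]
            if len(nuc):
                ring = np.vstack([nuc, nuc[:1]])
                ax.plot(ring[:, 0], ring[:, 1], **_STYLE["nucleus"])
            for fid in np.unique(frame.filament_id):
                if fid < 0:
                    continue
                idx = np.flatnonzero(frame.filament_id == fid)
                # chain order: shaft beads in index order (inserted beads are
                # appended chronologically just behind the head), head last
                head = idx[frame.role[idx] == int(Role.ACTIN_HEAD)]
                shaft = idx[frame.role[idx] != int(Role.ACTIN_HEAD)]
                fil = frame.positions[np.concatenate([shaft, head])]
                ax.plot(fil[:, 0], fil[:, 1], **_STYLE["filament"])
            heads = frame.positions[frame.role == int(Role.ACTIN_HEAD)]
            if len(heads):
                ax.scatter(heads[:, 0], heads[:, 1], zorder=3, **_STYLE["head"])
            ax.set_aspect("equal")
            ax.set_xlabel("x [sigma]")
            ax.set_ylabel("y [sigma]")
            ax.set_title(f"t = {frame.time:g} tau")
            metadata = {"Date": None} if path.suffix.lower() == ".svg" else None
            fig.savefig(path, metadata=metadata)
        finally:
            plt.close(fig)
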