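"""Shape quantification of simulated cells.

A protrusion is a circularly contiguous arc of membrane beads whose distance
from the membrane centroid exceeds the baseline radius (the *median* of the
radial profile, robust against the protrusion itself) by at least ``delta``.
The projection length — the headline readout of the sweeps — is the radial
excursion of the tip bead of the largest protrusion above that baseline.
All metrics are invariant under rigid rotation and translation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cell_builder import Configuration

__all__ = [
    "ProtrusionRecord",
    "MorphometricsResult",
    "radial_profile",
    "detect_protrusions",
    "projection_length",
    "circularity",
    "cell_area",
    "persistence",
    "measure_frame",
    "measure_trajectory",
]

DEFAULT_DELTA = 2.0  # excursion threshold [sigma]
DEFAULT_MIN_ARC = 2  # minimum beads per protrusion
DEFAULT_L_MIN = 2.0  # persistence length threshold [sigma]


@dataclass(frozen=True)
class ProtrusionRecord:
    """One detected protrusion on the membrane ring."""

    arc: tuple[int, ...]  # contiguous membrane-ring positions (ring order)
    tip_index: int  # ring position of maximal radial excursion
    length: float  # tip radial distance - baseline radius [sigma]
    base_width: float  # chord across the arc ends [sigma]


@dataclass(frozen=True)
class MorphometricsResult:
    """Per-frame shape metrics (persistence_fraction is trajectory-level)."""

    projection_length: float
    n_protrusions: int
    cell_area: float
    circularity: float
    persistence_fraction: float | None = None


def _membrane_positions(frame: Configuration) -> np.ndarray:
    pos = frame.positions[frame.membrane_indices()]
    if len(pos) < 3:
        raise ValueError("frame has fewer than 3 membrane beads")
    return pos


def radial_profile(frame: Configuration) -> np.ndarray:
    """Distance of each membrane bead from the membrane centroid, ring order."""
    pos = _membrane_positions(frame)
    centroid = pos.mean(axis=0)
    return np.linalg.norm(pos - centroid, axis=1)


def detect_protrusions(
    frame: Configuration,
    delta: float = DEFAULT_DELTA,
    min_arc: int = DEFAULT_MIN_ARC,
) -> list[ProtrusionRecord]:
    """Maximal contiguous supra-threshold arcs of the membrane ring.

    Baseline R0 is the median radial profile; beads with distance > R0 + delta
    form candidate arcs (circular indexing, so arcs may wrap position 0);
    arcs shorter than ``min_arc`` beads are discarded.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if min_arc < 1:
        raise ValueError("min_arc must be >= 1")
    r = radial_profile(frame)
    n = len(r)
    r0 = float(np.median(r))
    above = r > r0 + delta
    if not above.any():
        return []
    if above.all():
        # degenerate: whole ring above threshold; one arc covering the ring
        tip = int(np.argmax(r))
        return [
            ProtrusionRecord(
                arc=tuple(range(n)),
                tip_index=tip,
                length=float(r[tip] - r0),
                base_width=0.0,
            )
        ]

    # rotate so position 0 is below threshold, then find runs
    start = int(np.argmin(above))  # first False
    shifted = np.roll(above, -start)
    records: list[ProtrusionRecord] = []
    pos = _membrane_positions(frame)
    i = 0
    while i < n:
        if shifted[i]:
            j = i
            while j < n and shifted[j]:
                j += 1
            arc = tuple((start + k) % n for k in range(i, j))
            if len(arc) >= min_arc:
                arc_r = r[list(arc)]
                tip = arc[int(np.argmax(arc_r))]
                records.append(
                    ProtrusionRecord(
                        arc=arc,
                        tip_index=int(tip),
                        length=float(r[tip] - r0),
                        base_width=float(np.linalg.norm(pos[arc[0]] - pos[arc[-1]])),
                    )
                )
            i = j
        else:
            i += 1
    return records


def projection_length(
    frame: Configuration,
    delta: float = DEFAULT_DELTA,
    min_arc: int = DEFAULT_MIN_ARC,
) -> float:
    """Length of the largest protrusion, or 0.0 when none is detected."""
    records = detect_protrusions(frame, delta, min_arc)
    return max((rec.length for rec in records), default=0.0)


def cell_area(frame: Configuration) -> float:
    """Unsigned shoelace area of the membrane polygon [sigma^2]."""
    pos = _membrane_positions(frame)
    x, y = pos[:, 0], pos[:, 1]
    return abs(0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def circularity(frame: Configuration) -> float:
    """Shape factor 4 pi A / P^2 of the membrane polygon (1 = circle)."""
    pos = _membrane_positions(frame)
    a = cell_area(frame)
    perimeter = float(np.sum(np.linalg.norm(pos - np.roll(pos, -1, axis=0), axis=1)))
    if perimeter == 0.0 or a == 0.0:
        raise ValueError("degenerate membrane polygon")
    return 4.0 * np.pi * a / perimeter**2


def persistence(
    trajectory,
    window_fraction: float = 0.5,
    l_min: float = DEFAULT_L_MIN,
    delta: float = DEFAULT_DELTA,
    min_arc: int = DEFAULT_MIN_ARC,
) -> float:
    """Fraction of late-run frames carrying a supra-threshold protrusion.

    The window is the final ``window_fraction`` of saved frames; a frame
    counts when its projection length exceeds ``l_min``.
    """
    if not 0.0 < window_fraction <= 1.0:
        raise ValueError("window_fraction must be in (0, 1]")
    if l_min <= 0:
        raise ValueError("l_min must be > 0")
    frames = trajectory.frames
    k = int(np.ceil(window_fraction * len(frames)))
    window = frames[len(frames) - k :]
    if len(window) < 2:
        raise ValueError("persistence window contains fewer than 2 frames")
    hits = sum(1 for f in window if projection_length(f, delta, min_arc) > l_min)
    return hits / len(window)


def measure_frame(
    frame: Configuration,
    delta: float = DEFAULT_DELTA,
    min_arc: int = DEFAULT_MIN_ARC,
) -> MorphometricsResult:
    records = detect_protrusions(frame, delta, min_arc)
    return MorphometricsResult(
        projection_length=max((r.length for r in records), default=0.0),
        n_protrusions=len(records),
        cell_area=cell_area(frame),
        circularity=circularity(frame),
    )


def measure_trajectory(
    trajectory,
    delta: float = DEFAULT_DELTA,
    min_arc: int = DEFAULT_MIN_ARC,
    window_fraction: float = 0.5,
    l_min: float = DEFAULT_L_MIN,
):
    """Per-frame metrics table plus the trajectory-level persistence fraction.

    Returns (pandas.DataFrame, persistence_fraction); the frame columns are
    frame_time, projection_length, n_protrusions, cell_area, circularity.
    """
    import pandas as pd

    rows = []
    for f in trajectory.frames:
        m = measure_frame(f, delta, min_arc)
        rows.append(
            {
                "frame_time": f.time,
                "projection_length": m.projection_length,
                "n_protrusions": m.n_protrusions,
                "cell_area": m.cell_area,
                "circularity": m.circularity,
            }
        )
    table = pd.DataFrame(rows)
    pf = persistence(trajectory, window_fraction, l_min, delta, min_arc)
    return table, pf
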