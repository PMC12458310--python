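"""(U3 x kappa00) parameter sweeps with replicate seeds.

Two presets ship with the package:

* ``fig1e`` — stiff membrane (kappa00 = 500), adhesion u3 in {3.0, 30.0}:
  low cortical tension permits dynamic protrusions (high persistence), high
  cortical tension clamps the membrane to the cortex (low persistence).
* ``fig1f`` — soft membrane (kappa00 = 10), a log-spaced u3 grid bracketing
  3.0 and 30.0: intermediate adhesion maximizes projection length, while very
  low or very high adhesion restricts it.

The headline statistic per run is the time-mean projection length over the
final half of saved frames; the final-frame and maximal values are recorded
alongside.  Replicate r uses seed root_seed + r, identical across grid points.
"""
from __future__ import annotations

import importlib.resources
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .config import SimulationConfig
from .dynamics import run_simulation
from .morphometrics import (
    DEFAULT_DELTA,
    DEFAULT_L_MIN,
    DEFAULT_MIN_ARC,
    projection_length,
)

__all__ = [
    "SweepSpec",
    "SweepRow",
    "run_sweep",
    "summarize",
    "rows_to_frame",
    "fig1e_preset",
    "fig1f_preset",
    "load_sweep_spec",
    "save_sweep_spec",
]

logger = logging.getLogger(__name__)


@dataclass
class SweepSpec:
    """A (u3 x kappa00) grid with replicate seeds over a base configuration."""

    base_config: SimulationConfig
    u3_values: list[float]
    kappa00_values: list[float]
    replicates: int = 5
    root_seed: int = 0

    def validate(self) -> None:
        if not self.u3_values or not self.kappa00_values:
            raise ValueError("u3_values and kappa00_values must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        self.base_config.require_valid()


@dataclass(frozen=True)
class SweepRow:
    """Outcome of one grid point x replicate."""

    u3: float
    kappa00: float
    replicate_seed: int
    projection_length_mean: float  # time-mean over the final half of frames
    projection_length_final: float
    projection_length_max: float
    persistence_fraction: float


def _measure_run(
    config: SimulationConfig,
    delta: float,
    min_arc: int,
    l_min: float,
) -> tuple[float, float, float, float]:
    traj = run_simulation(config)
    proj = np.array([projection_length(f, delta, min_arc) for f in traj.frames])
    k = int(np.ceil(0.5 * len(proj)))
    window = proj[len(proj) - k :]
    return (
        float(window.mean()),
        float(proj[-1]),
        float(proj.max()),
        float(np.mean(window > l_min)),
    )


def run_sweep(
    spec: SweepSpec,
    delta: float = DEFAULT_DELTA,
    min_arc: int = DEFAULT_MIN_ARC,
    l_min: float = DEFAULT_L_MIN,
    log_progress: bool = False,
) -> list[SweepRow]:
    """One SweepRow per (u3, kappa00, replicate), in deterministic grid order."""
    spec.validate()
    rows: list[SweepRow] = []
    for u3 in spec.u3_values:
        for kappa00 in spec.kappa00_values:
            for rep in range(spec.replicates):
                seed = spec.root_seed + rep
                config = spec.base_config.replace(u3=u3, kappa00=kappa00, seed=seed)
                try:
                    pm, pf, px, pers = _measure_run(config, delta, min_arc, l_min)
                except Exception as exc:
                    raise RuntimeError(
                        f"sweep failed at u3={u3}, kappa00={kappa00}, seed={seed}: {exc}"
                    ) from exc
                rows.append(SweepRow(u3, kappa00, seed, pm, pf, px, pers))
                if log_progress:
                    logger.info(
                        "u3=%g kappa00=%g seed=%d proj_mean=%.3f persistence=%.2f",
                        u3, kappa00, seed, pm, pers,
                    )
    return rows


def rows_to_frame(rows: list[SweepRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "u3": [r.u3 for r in rows],
            "kappa00": [r.kappa00 for r in rows],
            "seed": [r.replicate_seed for r in rows],
            "proj_mean": [r.projection_length_mean for r in rows],
            "proj_final": [r.projection_length_final for r in rows],
            "proj_max": [r.projection_length_max for r in rows],
            "persistence": [r.persistence_fraction for r in rows],
        }
    )


def summarize(rows: list[SweepRow], statistic: str = "proj_mean") -> pd.DataFrame:
    """Mean and SEM (sample SD / sqrt(n)) of ``statistic`` per grid point.

    A single-replicate grid point gets SEM 0 by convention and is flagged in
    the ``single_replicate`` column.
    """
    table = rows_to_frame(rows)
    if statistic not in table.columns:
        raise ValueError(f"unknown statistic {statistic!r}")
    out = []
    for (u3, kappa00), grp in table.groupby(["u3", "kappa00"], sort=True):
        vals = grp[statistic].to_numpy()
        n = len(vals)
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        if n == 1:
            logger.warning("grid point u3=%g kappa00=%g has a single replicate", u3, kappa00)
        out.append(
            {
                "u3": u3,
                "kappa00": kappa00,
                "n": n,
                "mean": float(vals.mean()),
                "sem": sem,
                "single_replicate": n == 1,
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# preset plumbing


def _spec_to_dict(spec: SweepSpec) -> dict:
    return {
        "base_config": spec.base_config.to_dict(),
        "u3_values": list(spec.u3_values),
        "kappa00_values": list(spec.kappa00_values),
        "replicates": spec.replicates,
        "root_seed": spec.root_seed,
    }


def _spec_from_dict(data: dict) -> SweepSpec:
    known = {"base_config", "u3_values", "kappa00_values", "replicates", "root_seed"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown sweep-spec keys: {sorted(unknown)}")
    spec = SweepSpec(
        base_config=SimulationConfig.from_dict(data.get("base_config", {})),
        u3_values=[float(v) for v in data["u3_values"]],
        kappa00_values=[float(v) for v in data["kappa00_values"]],
        replicates=int(data.get("replicates", 5)),
        root_seed=int(data.get("root_seed", 0)),
    )
    spec.validate()
    return spec


def load_sweep_spec(path: str | pathlib.Path) -> SweepSpec:
    data = yaml.safe_load(pathlib.Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping")
    return _spec_from_dict(data)


def save_sweep_spec(spec: SweepSpec, path: str | pathlib.Path) -> None:
    pathlib.Path(path).write_text(yaml.safe_dump(_spec_to_dict(spec), sort_keys=False))


def _load_preset(name: str) -> SweepSpec:
    ref = importlib.resources.files("neuritesim") / "presets" / f"{name}.yaml"
    return _spec_from_dict(yaml.safe_load(ref.read_text()))


def fig1e_preset() -> SweepSpec:
    """Stiff membrane (kappa00=500), u3 in {3.0, 30.0}: persistence contrast."""
    return _load_preset("fig1e")


def fig1f_preset() -> SweepSpec:
    """Soft membrane (kappa00=10), log-spaced u3 grid: interior maximum."""
    return _load_preset("fig1f")
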