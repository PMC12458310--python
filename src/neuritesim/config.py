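"""Simulation parameters.

All quantities are in reduced units: the bead diameter sigma is the length
unit, the thermal energy kT the energy unit, and the drag coefficient gamma
the friction unit, so the natural time unit is tau = gamma * sigma**2 / kT.
The two biophysical control parameters are

* ``u3`` — the membrane/actin-head adhesion well depth, a proxy for cortical
  (membrane-actin) tension, and
* ``kappa00`` — the stretching constant of membrane-membrane springs, a proxy
  for in-plane membrane tension.
"""
from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass

import yaml

__all__ = ["SimulationConfig", "load_config", "save_config"]


@dataclass
class SimulationConfig:
    """All model and run parameters for one cell simulation.

    Defaults assemble a 700-bead cell: 240 plasma-membrane beads, 80
    nuclear-envelope beads and 20 radial actin filaments of 19 beads each
    (head included).
    """

    # -- architecture -------------------------------------------------------
    n_membrane: int = 240
    n_nucleus: int = 80
    n_filaments: int = 20
    beads_per_filament: int = 19
    r_cell: float = 24.0
    r_nucleus: float = 8.0

    # -- interaction strengths ----------------------------------------------
    u3: float = 3.0
    kappa00: float = 10.0
    kappa_nuc: float = 100.0
    kappa_fil: float = 100.0
    kappa_bend_mem: float = 5.0
    kappa_bend_fil: float = 20.0
    kappa_bend_protrusive: float = 200.0
    kappa_area: float = 50.0
    sigma: float = 1.0
    eps_rep: float = 1.0

    # -- thermodynamics / integration ---------------------------------------
    kT: float = 1.0
    gamma: float = 1.0
    # stability: the stiffest default term (protrusive-filament bending) has a
    # Hessian eigenvalue ~16 kappa_b / a^2 ~ 5e3 kT/sigma^2; overdamped Euler
    # needs dt < 2 gamma / k, so 1e-4 tau keeps a ~4x safety margin
    dt: float = 1e-4
    n_steps: int = 10_000
    save_every: int = 500
    seed: int = 0

    # -- protrusive growth ---------------------------------------------------
    protrusive_count: int = 1
    grow_interval: float = 50.0
    grow_max: int = 30

    # ------------------------------------------------------------------
    @property
    def total_beads(self) -> int:
        return self.n_membrane + self.n_nucleus + self.n_filaments * self.beads_per_filament

    def validate(self) -> list[str]:
        """Return a list of violated invariants (empty means valid)."""
        problems: list[str] = []
        if self.n_membrane < 3:
            problems.append("n_membrane must be >= 3")
        if self.n_nucleus < 3:
            problems.append("n_nucleus must be >= 3")
        if self.n_filaments < 0:
            problems.append("n_filaments must be >= 0")
        if self.beads_per_filament < 2:
            problems.append("beads_per_filament must be >= 2")
        if not self.r_nucleus < self.r_cell:
            problems.append("r_nucleus must be < r_cell")
        if self.u3 < 0:
            problems.append("u3 must be >= 0")
        if self.kappa00 <= 0:
            problems.append("kappa00 must be > 0")
        if self.dt <= 0:
            problems.append("dt must be > 0")
        if self.sigma <= 0:
            problems.append("sigma must be > 0")
        if self.gamma <= 0:
            problems.append("gamma must be > 0")
        if self.kT < 0:
            problems.append("kT must be >= 0")
        if self.n_steps < 0:
            problems.append("n_steps must be >= 0")
        if self.save_every < 1:
            problems.append("save_every must be >= 1")
        if self.protrusive_count < 0 or self.protrusive_count > self.n_filaments:
            problems.append("protrusive_count must be in [0, n_filaments]")
        if self.grow_interval <= 0:
            problems.append("grow_interval must be > 0")
        if self.grow_max < 0:
            problems.append("grow_max must be >= 0")
        return problems

    def require_valid(self) -> "SimulationConfig":
        problems = self.validate()
        if problems:
            raise ValueError("invalid SimulationConfig: " + "; ".join(problems))
        return self

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def load_config(path: str | pathlib.Path) -> SimulationConfig:
    """Load a SimulationConfig from a flat YAML (or JSON) key-value file.

    Keys must be SimulationConfig field names; unknown keys are an error.
    """
    text = pathlib.Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of config keys to values")
    return SimulationConfig.from_dict(data).require_valid()


def save_config(config: SimulationConfig, path: str | pathlib.Path) -> None:
    path = pathlib.Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(config.to_dict(), indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
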