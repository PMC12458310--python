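"""Potential-energy terms and analytic forces — single source of truth.

Force field (reduced units):

* stretch        E = 1/2 kappa (r - r0)^2                (all springs)
* bend           E = kappa_b (1 - cos(phi - phi0))       (signed turning angle;
                 phi0 = 0 for filaments reduces to kappa_b (1 + cos theta)
                 with theta the interior angle)
* adhesion       truncated-shifted Lennard-Jones of depth u3, cutoff 2.5 sigma,
                 ACTIN_HEAD <-> MEMBRANE pairs only (cortical tension proxy)
* excluded vol.  WCA: purely repulsive LJ truncated at 2^(1/6) sigma
* area           E = 1/2 kappa_A (A - A0)^2 / A0, shoelace polygon area,
                 for the membrane and nucleus rings

Nonbonded terms skip 1-2 (bonded) and 1-3 (angle) pairs.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from . import _kernels
from .cell_builder import Configuration, Role, Topology
from .config import SimulationConfig

__all__ = [
    "EnergyBreakdown",
    "stretch_energy",
    "bend_energy",
    "attraction_energy",
    "repulsion_energy",
    "area_energy",
    "compute_forces",
    "total_energy",
    "PackedTopology",
    "pack_topology",
]

WCA_CUT_FACTOR = _kernels.WCA_CUT_FACTOR


@dataclass(frozen=True)
class EnergyBreakdown:
    """Potential energy by term [kT]; ``total`` is their sum."""

    stretch: float
    bend: float
    attraction: float
    repulsion: float
    area: float

    @property
    def total(self) -> float:
        return self.stretch + self.bend + self.attraction + self.repulsion + self.area

    def as_dict(self) -> dict[str, float]:
        return {
            "stretch": self.stretch,
            "bend": self.bend,
            "attraction": self.attraction,
            "repulsion": self.repulsion,
            "area": self.area,
            "total": self.total,
        }


def stretch_energy(r: float, kappa: float, r0: float) -> float:
    """Harmonic spring energy 1/2 kappa (r - r0)^2."""
    return 0.5 * kappa * (r - r0) ** 2


def bend_energy(theta: float, kappa_b: float, theta0: float = np.pi) -> float:
    """Discrete bending energy kappa_b (1 - cos(theta - theta0)).

    ``theta`` is the interior angle at the middle bead; with the default
    spontaneous angle theta0 = pi (straight chain) this is kappa_b (1 + cos
    theta), zero for collinear triples.  Rings use theta0 from the as-built
    geometry so the closed ring is relaxed.
    """
    return kappa_b * (1.0 - np.cos(theta - theta0))


def _lj(r: float, eps: float, sigma: float) -> float:
    sr6 = (sigma / r) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6)


def attraction_energy(r: float, u3: float, sigma: float = 1.0) -> float:
    """Head-membrane adhesion: LJ of depth u3, truncated and shifted at 2.5 sigma."""
    rc = 2.5 * sigma
    if r >= rc:
        return 0.0
    return _lj(r, u3, sigma) - _lj(rc, u3, sigma)


def repulsion_energy(r: float, eps_rep: float, sigma: float = 1.0) -> float:
    """WCA excluded volume: 4 eps [(s/r)^12 - (s/r)^6] + eps below 2^(1/6) sigma."""
    if r >= WCA_CUT_FACTOR * sigma:
        return 0.0
    return _lj(r, eps_rep, sigma) + eps_rep


def polygon_area(ring_positions: np.ndarray) -> float:
    """Signed shoelace area of an ordered 2D ring (positive if CCW)."""
    p = np.asarray(ring_positions, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def area_energy(ring_positions: np.ndarray, kappa_area: float, a0: float) -> float:
    """Quadratic area constraint 1/2 kappa_A (A - A0)^2 / A0."""
    if len(ring_positions) < 3:
        raise ValueError("area ring needs at least 3 points")
    if a0 == 0.0:
        raise ValueError("degenerate ring: target area is zero")
    area = polygon_area(ring_positions)
    if area == 0.0 and not np.allclose(a0, 0.0):
        # still well-defined, but flag a collapsed ring for the caller's logs
        pass
    return 0.5 * kappa_area * (area - a0) ** 2 / a0


class PackedTopology(NamedTuple):
    """Topology flattened into kernel-ready arrays for a fixed bead count."""

    bonds: np.ndarray
    bond_kappa: np.ndarray
    bond_r0: np.ndarray
    triples: np.ndarray
    triple_kappa: np.ndarray
    triple_phi0: np.ndarray
    area_idx: np.ndarray
    area_off: np.ndarray
    area_kappa: np.ndarray
    area_a0: np.ndarray
    excl: np.ndarray  # (n, n) uint8; 1-2 and 1-3 pairs plus the diagonal
    is_head: np.ndarray
    is_mem: np.ndarray


def pack_topology(topology: Topology, role: np.ndarray) -> PackedTopology:
    n = len(role)
    excl = np.zeros((n, n), dtype=np.uint8)
    np.fill_diagonal(excl, 1)
    b = topology.bonds
    if b.size:
        excl[b[:, 0], b[:, 1]] = 1
        excl[b[:, 1], b[:, 0]] = 1
    # 1-3 pairs are excluded on filaments only: bead insertion makes filament
    # 1-3 distances sub-sigma by construction, while ring 1-3 repulsion is what
    # gives the membrane its self-volume (without it, deep adhesion wells can
    # pile membrane beads on top of each other)
    t = topology.triples
    for a in range(len(t)):
        mid = t[a, 1]
        if role[mid] == int(Role.ACTIN) or role[mid] == int(Role.ACTIN_HEAD):
            excl[t[a, 0], t[a, 2]] = 1
            excl[t[a, 2], t[a, 0]] = 1

    if topology.area_groups:
        area_idx = np.concatenate([g.indices for g in topology.area_groups]).astype(np.int64)
        area_off = np.cumsum([0] + [len(g.indices) for g in topology.area_groups]).astype(np.int64)
        area_kappa = np.array([g.kappa for g in topology.area_groups], dtype=float)
        area_a0 = np.array([g.target_area for g in topology.area_groups], dtype=float)
    else:
        area_idx = np.zeros(0, dtype=np.int64)
        area_off = np.zeros(1, dtype=np.int64)
        area_kappa = np.zeros(0)
        area_a0 = np.zeros(0)

    return PackedTopology(
        bonds=np.ascontiguousarray(topology.bonds, dtype=np.int64).reshape(-1, 2),
        bond_kappa=np.asarray(topology.bond_kappa, dtype=float),
        bond_r0=np.asarray(topology.bond_r0, dtype=float),
        triples=np.ascontiguousarray(topology.triples, dtype=np.int64).reshape(-1, 3),
        triple_kappa=np.asarray(topology.triple_kappa, dtype=float),
        triple_phi0=np.asarray(topology.triple_phi0, dtype=float),
        area_idx=area_idx,
        area_off=area_off,
        area_kappa=area_kappa,
        area_a0=area_a0,
        excl=excl,
        is_head=(role == int(Role.ACTIN_HEAD)),
        is_mem=(role == int(Role.MEMBRANE)),
    )


class OverlapError(RuntimeError):
    """Two nonbonded beads closer than 1e-6 sigma."""


def compute_forces(
    configuration: Configuration,
    topology: Topology,
    config: SimulationConfig,
    packed: PackedTopology | None = None,
) -> tuple[np.ndarray, EnergyBreakdown]:
    """Analytic forces (= -grad E) and the energy breakdown for one frame."""
    pos = np.ascontiguousarray(configuration.positions, dtype=float)
    n = len(pos)
    if packed is None:
        packed = pack_topology(topology, configuration.role)

    cutoff = max(topology.attraction.cutoff, WCA_CUT_FACTOR * config.sigma)
    max_pairs = max(64, 80 * n)
    pi = np.empty(max_pairs, dtype=np.int64)
    pj = np.empty(max_pairs, dtype=np.int64)
    pt = np.empty(max_pairs, dtype=np.int8)
    n_pairs = _kernels.build_pairs(
        pos, cutoff, packed.excl, packed.is_head, packed.is_mem, pi, pj, pt
    )
    while n_pairs < 0:  # buffer overflow: grow and retry
        max_pairs *= 2
        pi = np.empty(max_pairs, dtype=np.int64)
        pj = np.empty(max_pairs, dtype=np.int64)
        pt = np.empty(max_pairs, dtype=np.int8)
        n_pairs = _kernels.build_pairs(
            pos, cutoff, packed.excl, packed.is_head, packed.is_mem, pi, pj, pt
        )

    forces = np.zeros_like(pos)
    es, eb, ea, er, earea, err_i, err_j = _kernels.forces_energy(
        pos,
        packed.bonds,
        packed.bond_kappa,
        packed.bond_r0,
        packed.triples,
        packed.triple_kappa,
        packed.triple_phi0,
        packed.area_idx,
        packed.area_off,
        packed.area_kappa,
        packed.area_a0,
        pi,
        pj,
        pt,
        n_pairs,
        topology.attraction.u3,
        topology.attraction.cutoff,
        config.eps_rep,
        config.sigma,
        forces,
    )
    if err_i >= 0:
        raise OverlapError(f"nonbonded beads {err_i} and {err_j} closer than 1e-6 sigma")
    return forces, EnergyBreakdown(es, eb, ea, er, earea)


def total_energy(
    configuration: Configuration,
    topology: Topology,
    config: SimulationConfig,
    packed: PackedTopology | None = None,
) -> float:
    _, breakdown = compute_forces(configuration, topology, config, packed)
    return breakdown.total
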