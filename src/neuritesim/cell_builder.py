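"""Initial-cell assembly.

The model cell is planar: a closed ring of plasma-membrane beads, a smaller
concentric ring of nuclear-envelope beads, and radial actin filaments whose
base bead is anchored to the nearest nuclear bead and whose outermost bead is
an actin *head* — the only species that adheres to the membrane (well depth
``u3``).  All bonded rest lengths, spontaneous bending angles and target ring
areas are taken from the as-built geometry, so the initial state is exactly
relaxed for every bonded and area term; only the nonbonded tail (head-membrane
adhesion, excluded volume) carries energy at t = 0.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig

__all__ = [
    "Role",
    "Configuration",
    "AreaGroup",
    "AttractionRule",
    "Topology",
    "build_cell",
    "validate_cell",
    "HEAD_INSET",
    "ANCHOR_GAP",
]

# Radial gap between the filament head and the membrane ring, chosen at the
# Lennard-Jones minimum so the adhesion exerts no initial radial jolt.
HEAD_INSET = 2.0 ** (1.0 / 6.0)
# Radial gap between the filament base bead and the nuclear ring.
ANCHOR_GAP = 1.0

ATTRACTION_CUTOFF_FACTOR = 2.5  # adhesion range, units of sigma


class Role(enum.IntEnum):
    MEMBRANE = 0
    NUCLEUS = 1
    ACTIN = 2
    ACTIN_HEAD = 3


# one-letter species codes used by the extended-XYZ writer
ROLE_SYMBOL = {Role.MEMBRANE: "M", Role.NUCLEUS: "N", Role.ACTIN: "A", Role.ACTIN_HEAD: "H"}
SYMBOL_ROLE = {v: k for k, v in ROLE_SYMBOL.items()}


@dataclass
class Configuration:
    """One frame of bead state (2D positions; velocities used only in NVE mode)."""

    positions: np.ndarray  # (n, 2) float64, units sigma
    velocities: np.ndarray  # (n, 2) float64; zero outside NVE mode
    role: np.ndarray  # (n,) int8, values from Role
    filament_id: np.ndarray  # (n,) int32; -1 for non-filament beads
    time: float = 0.0

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def copy(self) -> "Configuration":
        return Configuration(
            self.positions.copy(),
            self.velocities.copy(),
            self.role.copy(),
            self.filament_id.copy(),
            self.time,
        )

    def membrane_indices(self) -> np.ndarray:
        return np.flatnonzero(self.role == int(Role.MEMBRANE))


@dataclass
class AreaGroup:
    """An ordered index cycle constrained to a target enclosed area."""

    indices: np.ndarray  # ring order
    kappa: float
    target_area: float


@dataclass
class AttractionRule:
    """ACTIN_HEAD <-> MEMBRANE adhesion: truncated-shifted LJ of depth u3."""

    u3: float
    cutoff: float  # absolute distance, 2.5 * sigma


@dataclass
class Topology:
    """Bonded terms, nonbonded rules and area constraints of one cell."""

    bonds: np.ndarray  # (nb, 2) int32
    bond_kappa: np.ndarray  # (nb,)
    bond_r0: np.ndarray  # (nb,)
    triples: np.ndarray  # (nt, 3) int32; middle bead second
    triple_kappa: np.ndarray
    triple_phi0: np.ndarray  # spontaneous signed turning angle [rad]
    attraction: AttractionRule
    area_groups: list[AreaGroup] = field(default_factory=list)
    filament_rest_length: float = 0.0  # native segment rest length [sigma]

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def exclusion_pairs(self, role: np.ndarray) -> set[tuple[int, int]]:
        """Unordered pairs excluded from nonbonded terms.

        All 1-2 (bonded) pairs, plus 1-3 (angle) pairs on filaments — growth
        insertion makes filament 1-3 distances sub-sigma, whereas ring 1-3
        repulsion provides the membrane's self-volume and is kept.
        """
        pairs: set[tuple[int, int]] = set()
        for i, j in self.bonds:
            pairs.add((min(i, j), max(i, j)))
        for i, mid, k in self.triples:
            if role[mid] in (int(Role.ACTIN), int(Role.ACTIN_HEAD)):
                pairs.add((min(i, k), max(i, k)))
        return pairs

    def copy(self) -> "Topology":
        return Topology(
            self.bonds.copy(),
            self.bond_kappa.copy(),
            self.bond_r0.copy(),
            self.triples.copy(),
            self.triple_kappa.copy(),
            self.triple_phi0.copy(),
            AttractionRule(self.attraction.u3, self.attraction.cutoff),
            [AreaGroup(g.indices.copy(), g.kappa, g.target_area) for g in self.area_groups],
            self.filament_rest_length,
        )


def _ring_positions(n: int, radius: float) -> np.ndarray:
    angles = 2.0 * np.pi * np.arange(n) / n
    return radius * np.stack([np.cos(angles), np.sin(angles)], axis=1)


def build_cell(config: SimulationConfig) -> tuple[Configuration, Topology]:
    """Assemble the initial cell and its interaction topology.

    Raises ValueError on an invalid config or geometric infeasibility
    (bead spacing below 0.5 sigma on either ring).
    """
    config.require_valid()
    sig = config.sigma

    mem_spacing = 2.0 * config.r_cell * np.sin(np.pi / config.n_membrane)
    nuc_spacing = 2.0 * config.r_nucleus * np.sin(np.pi / config.n_nucleus)
    if mem_spacing < 0.5 * sig:
        raise ValueError(
            f"membrane ring infeasible: bead spacing {mem_spacing:.3f} < 0.5 sigma "
            f"(n_membrane={config.n_membrane}, r_cell={config.r_cell})"
        )
    if nuc_spacing < 0.5 * sig:
        raise ValueError(
            f"nucleus ring infeasible: bead spacing {nuc_spacing:.3f} < 0.5 sigma "
            f"(n_nucleus={config.n_nucleus}, r_nucleus={config.r_nucleus})"
        )

    n_mem, n_nuc = config.n_membrane, config.n_nucleus
    n_fil, bpf = config.n_filaments, config.beads_per_filament
    n_total = config.total_beads

    positions = np.empty((n_total, 2))
    role = np.empty(n_total, dtype=np.int8)
    filament_id = np.full(n_total, -1, dtype=np.int32)

    positions[:n_mem] = _ring_positions(n_mem, config.r_cell)
    role[:n_mem] = int(Role.MEMBRANE)
    positions[n_mem : n_mem + n_nuc] = _ring_positions(n_nuc, config.r_nucleus)
    role[n_mem : n_mem + n_nuc] = int(Role.NUCLEUS)

    r_base = config.r_nucleus + ANCHOR_GAP * sig
    r_head = config.r_cell - HEAD_INSET * sig
    if r_head <= r_base:
        raise ValueError("filaments infeasible: head radius <= base radius")
    radii = np.linspace(r_base, r_head, bpf)
    fil_rest = float(radii[1] - radii[0]) if bpf > 1 else 0.0

    offset = n_mem + n_nuc
    for k in range(n_fil):
        ang = 2.0 * np.pi * k / n_fil
        sl = slice(offset + k * bpf, offset + (k + 1) * bpf)
        positions[sl, 0] = radii * np.cos(ang)
        positions[sl, 1] = radii * np.sin(ang)
        role[sl] = int(Role.ACTIN)
        role[offset + (k + 1) * bpf - 1] = int(Role.ACTIN_HEAD)
        filament_id[sl] = k

    # ---- bonds -------------------------------------------------------------
    bonds, kap, r0 = [], [], []

    def add_ring_bonds(start: int, n: int, kappa: float) -> None:
        for a in range(n):
            i, j = start + a, start + (a + 1) % n
            bonds.append((i, j))
            kap.append(kappa)
            r0.append(float(np.linalg.norm(positions[i] - positions[j])))

    add_ring_bonds(0, n_mem, config.kappa00)
    add_ring_bonds(n_mem, n_nuc, config.kappa_nuc)

    nuc_pos = positions[n_mem : n_mem + n_nuc]
    for k in range(n_fil):
        base = offset + k * bpf
        for a in range(bpf - 1):
            bonds.append((base + a, base + a + 1))
            kap.append(config.kappa_fil)
            r0.append(fil_rest)
        # anchor: base bead to nearest nuclear bead
        d = np.linalg.norm(nuc_pos - positions[base], axis=1)
        anchor = n_mem + int(np.argmin(d))
        bonds.append((anchor, base))
        kap.append(config.kappa_fil)
        r0.append(float(d.min()))

    # ---- bending triples ----------------------------------------------------
    triples, tkap, tphi0 = [], [], []

    def add_ring_triples(start: int, n: int, kappa_b: float) -> None:
        phi0 = 2.0 * np.pi / n  # CCW ring turning angle
        for a in range(n):
            i = start + (a - 1) % n
            j = start + a
            k2 = start + (a + 1) % n
            triples.append((i, j, k2))
            tkap.append(kappa_b)
            tphi0.append(phi0)

    add_ring_triples(0, n_mem, config.kappa_bend_mem)
    add_ring_triples(n_mem, n_nuc, config.kappa_bend_mem)

    for k in range(n_fil):
        base = offset + k * bpf
        kb = config.kappa_bend_protrusive if k < config.protrusive_count else config.kappa_bend_fil
        for a in range(1, bpf - 1):
            triples.append((base + a - 1, base + a, base + a + 1))
            tkap.append(kb)
            tphi0.append(0.0)

    # ---- area groups ---------------------------------------------------------
    def shoelace(p: np.ndarray) -> float:
        x, y = p[:, 0], p[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    mem_idx = np.arange(n_mem, dtype=np.int32)
    nuc_idx = np.arange(n_mem, n_mem + n_nuc, dtype=np.int32)
    area_groups = [
        AreaGroup(mem_idx, config.kappa_area, shoelace(positions[mem_idx])),
        AreaGroup(nuc_idx, config.kappa_area, shoelace(positions[nuc_idx])),
    ]

    topology = Topology(
        bonds=np.asarray(bonds, dtype=np.int32).reshape(-1, 2),
        bond_kappa=np.asarray(kap),
        bond_r0=np.asarray(r0),
        triples=np.asarray(triples, dtype=np.int32).reshape(-1, 3),
        triple_kappa=np.asarray(tkap),
        triple_phi0=np.asarray(tphi0),
        attraction=AttractionRule(config.u3, ATTRACTION_CUTOFF_FACTOR * sig),
        area_groups=area_groups,
        filament_rest_length=fil_rest,
    )
    configuration = Configuration(
        positions=positions,
        velocities=np.zeros_like(positions),
        role=role,
        filament_id=filament_id,
        time=0.0,
    )
    return configuration, topology


def validate_cell(
    config: SimulationConfig, configuration: Configuration, topology: Topology
) -> list[str]:
    """Check cell/topology invariants; returns violation messages (empty = valid).

    Never raises and never mutates its inputs.
    """
    report: list[str] = []
    n = configuration.n_beads

    if n != config.total_beads:
        report.append(f"bead count {n} != config total {config.total_beads}")

    counts = {r: int(np.sum(configuration.role == int(r))) for r in Role}
    if counts[Role.MEMBRANE] != config.n_membrane:
        report.append(f"membrane bead count {counts[Role.MEMBRANE]} != {config.n_membrane}")
    if counts[Role.NUCLEUS] != config.n_nucleus:
        report.append(f"nucleus bead count {counts[Role.NUCLEUS]} != {config.n_nucleus}")
    if counts[Role.ACTIN_HEAD] != config.n_filaments:
        report.append(f"actin-head count {counts[Role.ACTIN_HEAD]} != {config.n_filaments}")

    if not np.all(np.isfinite(configuration.positions)):
        bad = np.flatnonzero(~np.isfinite(configuration.positions).all(axis=1))
        report.append(f"non-finite coordinates at bead indices {bad.tolist()}")

    if topology.bonds.size:
        if topology.bonds.min() < 0 or topology.bonds.max() >= n:
            report.append("bond index out of range")
        else:
            seen: set[tuple[int, int]] = set()
            for i, j in topology.bonds:
                key = (min(int(i), int(j)), max(int(i), int(j)))
                if i == j:
                    report.append(f"self bond ({i},{j})")
                elif key in seen:
                    report.append(f"duplicate bond {key}")
                seen.add(key)
            d = np.linalg.norm(
                configuration.positions[topology.bonds[:, 0]]
                - configuration.positions[topology.bonds[:, 1]],
                axis=1,
            )
            with np.errstate(invalid="ignore"):
                coincident = np.flatnonzero(d == 0.0)
            for b in coincident:
                report.append(f"bonded beads at identical position: bond {tuple(topology.bonds[b])}")

    if topology.triples.size and (topology.triples.min() < 0 or topology.triples.max() >= n):
        report.append("bend triple index out of range")

    # ring closure: count intra-role ring bonds
    def ring_bond_count(role_value: int) -> int:
        r = configuration.role
        m = (r[topology.bonds[:, 0]] == role_value) & (r[topology.bonds[:, 1]] == role_value)
        return int(np.sum(m))

    if topology.bonds.size:
        if ring_bond_count(int(Role.MEMBRANE)) != config.n_membrane:
            report.append("membrane ring not closed: wrong membrane-membrane bond count")
        if ring_bond_count(int(Role.NUCLEUS)) != config.n_nucleus:
            report.append("nucleus ring not closed: wrong nucleus-nucleus bond count")

    if len(topology.area_groups) != 2:
        report.append(f"expected 2 area groups, found {len(topology.area_groups)}")
    for g in topology.area_groups:
        if len(g.indices) < 3:
            report.append("area group with fewer than 3 beads")

    return report
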