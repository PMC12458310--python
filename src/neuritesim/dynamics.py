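"""Time integration and trajectory production.

Production dynamics are overdamped Langevin (Euler-Maruyama):

    dx = F dt / gamma + sqrt(2 kT dt / gamma) xi,   xi ~ N(0, 1) per coordinate

which is the appropriate inertialess limit for cellular mechanics.  A
velocity-Verlet NVE mode exists purely to validate the force field by energy
conservation.  Designated *protrusive* filaments elongate by deterministic
bead insertion behind the head (a polymerization proxy); each insertion adds
one native segment of rest contour length, so the growing filament pushes its
head against the membrane.

Randomness: one ``numpy.random.default_rng(seed)`` (PCG64) stream per run;
Gaussian displacements are drawn per step for all beads in index order, x
component then y.  Identical (config, seed) gives bit-identical trajectories.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .cell_builder import Configuration, Role, Topology, build_cell
from .config import SimulationConfig
from .mechanics import (
    WCA_CUT_FACTOR,
    EnergyBreakdown,
    OverlapError,
    PackedTopology,
    compute_forces,
    pack_topology,
)

__all__ = [
    "Trajectory",
    "GrowthEvent",
    "step_overdamped",
    "step_nve",
    "grow_protrusive_filament",
    "run_simulation",
    "run_nve",
]

logger = logging.getLogger(__name__)

_SKIN = 0.4  # Verlet-list skin [sigma]
_MAX_CHUNK = 2000  # steps per kernel call (bounds the noise buffer)
MAX_DISPLACEMENT = 0.1  # cap on the deterministic per-step displacement [sigma]


@dataclass(frozen=True)
class GrowthEvent:
    time: float
    filament_id: int
    bead_index: int


@dataclass
class Trajectory:
    """Saved frames, energy breakdown per frame, and growth events of one run."""

    frames: list[Configuration]
    energies: list[EnergyBreakdown]
    config: SimulationConfig
    topology_events: list[GrowthEvent] = field(default_factory=list)
    topology: Topology | None = None

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


def step_overdamped(
    configuration: Configuration,
    forces: np.ndarray,
    dt: float,
    gamma: float,
    kT: float,
    rng: np.random.Generator,
    max_displacement: float = MAX_DISPLACEMENT,
) -> Configuration:
    """One Euler-Maruyama step; returns a new Configuration (velocities untouched).

    The deterministic displacement F dt/gamma is capped at
    ``max_displacement`` per bead (the cap engages only for forces far above
    the typical scale and keeps the steep adhesion core integrable; pass
    ``numpy.inf`` to disable).  Noise is drawn only when kT > 0, so an
    athermal run consumes no random numbers.
    """
    if dt <= 0 or gamma <= 0 or kT < 0:
        raise ValueError("require dt > 0, gamma > 0, kT >= 0")
    new = configuration.copy()
    disp = forces * (dt / gamma)
    norm = np.linalg.norm(disp, axis=1)
    over = norm > max_displacement
    if over.any():
        disp[over] *= (max_displacement / norm[over])[:, None]
    new.positions += disp
    if kT > 0:
        new.positions += np.sqrt(2.0 * kT * dt / gamma) * rng.standard_normal(
            configuration.positions.shape
        )
    if not np.all(np.isfinite(new.positions)):
        raise RuntimeError(f"non-finite displacement at t={configuration.time:g}")
    new.time = configuration.time + dt
    return new


def step_nve(
    configuration: Configuration,
    topology: Topology,
    config: SimulationConfig,
    dt: float,
    forces: np.ndarray | None = None,
) -> Configuration:
    """One velocity-Verlet step with unit bead mass (validation mode)."""
    if forces is None:
        forces, _ = compute_forces(configuration, topology, config)
    new = configuration.copy()
    new.velocities += 0.5 * dt * forces
    new.positions += dt * new.velocities
    if not np.all(np.isfinite(new.positions)):
        raise RuntimeError(f"non-finite displacement at t={configuration.time:g}")
    new_forces, _ = compute_forces(new, topology, config)
    new.velocities += 0.5 * dt * new_forces
    new.time = configuration.time + dt
    return new


def grow_protrusive_filament(
    configuration: Configuration,
    topology: Topology,
    config: SimulationConfig,
    time: float,
    event_log: list[GrowthEvent] | None = None,
) -> tuple[Configuration, Topology]:
    """Insert one bead behind the head of each protrusive filament.

    The new bead sits at the midpoint of the head and its inner neighbor; the
    two rewired bonds get the filament's native rest length, adding one
    segment of rest contour per event.  An insertion that would land within
    0.1 sigma of a non-bonded bead is skipped with a warning.  Returns new
    (Configuration, Topology); inputs are not mutated.
    """
    conf = configuration.copy()
    topo = topology.copy()
    for fid in range(config.protrusive_count):
        on_fil = conf.filament_id == fid
        added = int(np.sum(on_fil)) - config.beads_per_filament
        if added >= config.grow_max:
            continue
        head_candidates = np.flatnonzero(on_fil & (conf.role == int(Role.ACTIN_HEAD)))
        if len(head_candidates) != 1:
            raise ValueError(f"filament {fid}: expected exactly one head bead")
        head = int(head_candidates[0])

        bond_rows = np.flatnonzero((topo.bonds == head).any(axis=1))
        fil_rows = [
            int(b)
            for b in bond_rows
            if conf.filament_id[topo.bonds[b, 0]] == fid
            and conf.filament_id[topo.bonds[b, 1]] == fid
        ]
        if len(fil_rows) != 1:
            raise ValueError(f"filament {fid}: head must have exactly one filament bond")
        row = fil_rows[0]
        i, j = topo.bonds[row]
        neighbor = int(j if i == head else i)

        # polymerization stalls under load: insert only once the head segment
        # has relaxed back to (at least) its rest length, otherwise repeated
        # insertion into a jammed tip overcrowds beads without adding length
        head_gap = float(np.linalg.norm(conf.positions[head] - conf.positions[neighbor]))
        if head_gap < topo.filament_rest_length:
            logger.debug("t=%g filament %d: growth stalled (tip under load)", time, fid)
            continue

        new_pos = 0.5 * (conf.positions[head] + conf.positions[neighbor])
        others = np.ones(conf.n_beads, dtype=bool)
        others[head] = others[neighbor] = False
        d = np.linalg.norm(conf.positions[others] - new_pos, axis=1)
        if d.size and d.min() < 0.1 * config.sigma:
            logger.warning(
                "t=%g filament %d: insertion would overlap a non-bonded bead; skipped",
                time,
                fid,
            )
            continue

        new_index = conf.n_beads
        conf.positions = np.vstack([conf.positions, new_pos])
        conf.velocities = np.vstack([conf.velocities, np.zeros(2)])
        conf.role = np.append(conf.role, np.int8(int(Role.ACTIN)))
        conf.filament_id = np.append(conf.filament_id, np.int32(fid))

        r0 = topo.filament_rest_length
        topo.bonds[row] = (neighbor, new_index)
        topo.bond_r0[row] = r0
        topo.bond_kappa[row] = config.kappa_fil
        topo.bonds = np.vstack([topo.bonds, [[new_index, head]]]).astype(np.int32)
        topo.bond_kappa = np.append(topo.bond_kappa, config.kappa_fil)
        topo.bond_r0 = np.append(topo.bond_r0, r0)

        # rewire the bending triple that ended at the head, and add one at the
        # new bead; protrusive filaments use the stiffer bending constant
        tri = topo.triples
        hit = np.flatnonzero((tri[:, 1] == neighbor) & (tri[:, 2] == head))
        for h in hit:
            topo.triples[h, 2] = new_index
        kb = config.kappa_bend_protrusive
        topo.triples = np.vstack([topo.triples, [[neighbor, new_index, head]]]).astype(np.int32)
        topo.triple_kappa = np.append(topo.triple_kappa, kb)
        topo.triple_phi0 = np.append(topo.triple_phi0, 0.0)

        if event_log is not None:
            event_log.append(GrowthEvent(time, fid, new_index))
    return conf, topo


class _KernelState:
    """Mutable per-run kernel buffers tied to the current bead count."""

    def __init__(self, pos: np.ndarray, packed: PackedTopology, config: SimulationConfig,
                 rcut_attr: float):
        n = len(pos)
        self.list_cutoff = max(rcut_attr, WCA_CUT_FACTOR * config.sigma) + _SKIN * config.sigma
        self.max_pairs = max(256, 80 * n)
        self.pi = np.empty(self.max_pairs, dtype=np.int64)
        self.pj = np.empty(self.max_pairs, dtype=np.int64)
        self.pt = np.empty(self.max_pairs, dtype=np.int8)
        self.forces = np.zeros((n, 2))
        self.ref_pos = pos.copy()
        self.packed = packed
        self.rcut_attr = rcut_attr
        self.n_pairs = self._build(pos)

    def _build(self, pos: np.ndarray) -> int:
        while True:
            n = _kernels.build_pairs(
                pos, self.list_cutoff, self.packed.excl, self.packed.is_head,
                self.packed.is_mem, self.pi, self.pj, self.pt,
            )
            if n >= 0:
                self.ref_pos[:] = pos
                return n
            self.max_pairs *= 2
            self.pi = np.empty(self.max_pairs, dtype=np.int64)
            self.pj = np.empty(self.max_pairs, dtype=np.int64)
            self.pt = np.empty(self.max_pairs, dtype=np.int8)


def run_simulation(config: SimulationConfig, log_progress: bool = False) -> Trajectory:
    """Build the cell and integrate ``config.n_steps`` of overdamped dynamics.

    Frames (and the energy breakdown) are saved at step 0, every
    ``save_every`` steps, and at the final step.  Protrusive-filament growth
    events fire each time the simulation clock passes a multiple of
    ``grow_interval``, up to ``grow_max`` insertions per filament.  Output is
    a deterministic function of (config, seed).
    """
    config.require_valid()
    configuration, topology = build_cell(config)
    rng = np.random.default_rng(config.seed)
    dt, gamma, kT = config.dt, config.gamma, config.kT
    noise_scale = np.sqrt(2.0 * kT * dt / gamma)

    # growth schedule in step indices (clock crosses m * grow_interval); the
    # per-filament grow_max cap and the stall rule live in the growth op
    grow_steps: list[int] = []
    if config.protrusive_count > 0 and config.grow_max > 0:
        m = 1
        while True:
            s = int(np.ceil(m * config.grow_interval / dt - 1e-9))
            if s > config.n_steps:
                break
            if s > 0:
                grow_steps.append(s)
            m += 1
        grow_steps = sorted(set(grow_steps))

    packed = pack_topology(topology, configuration.role)
    state = _KernelState(configuration.positions, packed, config, topology.attraction.cutoff)

    traj = Trajectory(frames=[], energies=[], config=config, topology_events=[])

    def save_frame() -> None:
        frame = configuration.copy()
        traj.frames.append(frame)
        _, breakdown = compute_forces(frame, topology, config, packed)
        traj.energies.append(breakdown)
        if log_progress:
            from .morphometrics import detect_protrusions

            n_prot = len(detect_protrusions(frame))
            logger.info(
                "t=%.4g E=%.6g (stretch=%.3g bend=%.3g attr=%.3g rep=%.3g area=%.3g) "
                "protrusions=%d grown=%d",
                frame.time, breakdown.total, breakdown.stretch, breakdown.bend,
                breakdown.attraction, breakdown.repulsion, breakdown.area,
                n_prot, len(traj.topology_events),
            )

    save_frame()

    step = 0
    next_save = config.save_every
    grow_iter = iter(grow_steps)
    next_grow = next(grow_iter, None)

    while step < config.n_steps:
        stop = min(config.n_steps, next_save, step + _MAX_CHUNK)
        if next_grow is not None:
            stop = min(stop, next_grow)
        seg = stop - step
        if seg > 0:
            n = configuration.n_beads
            if kT > 0:
                noise = noise_scale * rng.standard_normal((seg, n, 2))
            else:
                noise = np.zeros((seg, n, 2))
            off = 0
            while off < seg:
                err, err_step, ei, ej, n_pairs = _kernels.integrate_overdamped_chunk(
                    configuration.positions, state.ref_pos,
                    state.pi, state.pj, state.pt, state.n_pairs,
                    packed.bonds, packed.bond_kappa, packed.bond_r0,
                    packed.triples, packed.triple_kappa, packed.triple_phi0,
                    packed.area_idx, packed.area_off, packed.area_kappa, packed.area_a0,
                    packed.excl, packed.is_head, packed.is_mem,
                    noise[off:], dt / gamma, MAX_DISPLACEMENT * config.sigma,
                    _SKIN * config.sigma, state.list_cutoff,
                    topology.attraction.u3, state.rcut_attr, config.eps_rep, config.sigma,
                    state.forces,
                )
                state.n_pairs = n_pairs
                if err == 0:
                    off = seg
                elif err == 3:  # pair buffer overflow: grow buffers, resume
                    state.max_pairs *= 2
                    state.pi = np.empty(state.max_pairs, dtype=np.int64)
                    state.pj = np.empty(state.max_pairs, dtype=np.int64)
                    state.pt = np.empty(state.max_pairs, dtype=np.int8)
                    state.n_pairs = state._build(configuration.positions)
                    off += err_step
                elif err == 1:
                    raise OverlapError(
                        f"step {step + off + err_step}: nonbonded beads {ei} and {ej} "
                        "closer than 1e-6 sigma"
                    )
                else:
                    raise RuntimeError(
                        f"step {step + off + err_step}: non-finite displacement"
                    )
            step = stop
            configuration.time = step * dt

        if step == next_save:
            save_frame()
            next_save += config.save_every
        if next_grow is not None and step == next_grow:
            n_before = configuration.n_beads
            configuration, topology = grow_protrusive_filament(
                configuration, topology, config, step * dt, traj.topology_events
            )
            if configuration.n_beads != n_before:
                packed = pack_topology(topology, configuration.role)
                state = _KernelState(
                    configuration.positions, packed, config, topology.attraction.cutoff
                )
            next_grow = next(grow_iter, None)

    if traj.frames[-1].time != configuration.time:
        save_frame()
    traj.topology = topology
    return traj


def run_nve(
    configuration: Configuration,
    topology: Topology,
    config: SimulationConfig,
    n_steps: int,
    dt: float,
    save_every: int = 100,
) -> tuple[np.ndarray, np.ndarray, Configuration]:
    """Velocity-Verlet run; returns (times, total energies, final state).

    Total energy = kinetic (unit mass) + potential.  Used to validate the
    force field: for small dt the drift of the returned series is bounded.
    """
    conf = configuration.copy()
    packed = pack_topology(topology, conf.role)
    state = _KernelState(conf.positions, packed, config, topology.attraction.cutoff)

    def total_e() -> float:
        _, br = compute_forces(conf, topology, config, packed)
        return 0.5 * float(np.sum(conf.velocities**2)) + br.total

    forces, _ = compute_forces(conf, topology, config, packed)
    state.forces[:] = forces

    times = [conf.time]
    energies = [total_e()]
    done = 0
    while done < n_steps:
        seg = min(save_every, n_steps - done)
        err, err_step, ei, ej, n_pairs = _kernels.integrate_nve_chunk(
            conf.positions, conf.velocities, state.ref_pos,
            state.pi, state.pj, state.pt, state.n_pairs,
            packed.bonds, packed.bond_kappa, packed.bond_r0,
            packed.triples, packed.triple_kappa, packed.triple_phi0,
            packed.area_idx, packed.area_off, packed.area_kappa, packed.area_a0,
            packed.excl, packed.is_head, packed.is_mem,
            seg, dt, _SKIN * config.sigma, state.list_cutoff,
            topology.attraction.u3, state.rcut_attr, config.eps_rep, config.sigma,
            state.forces,
        )
        state.n_pairs = n_pairs
        if err == 1:
            raise OverlapError(f"NVE step {done + err_step}: beads {ei}, {ej} overlap")
        if err == 2:
            raise RuntimeError(f"NVE step {done + err_step}: non-finite displacement")
        if err == 3:
            # cannot resume mid velocity-Verlet step; buffers are sized 80n so
            # this indicates a pathological configuration
            raise RuntimeError(f"NVE step {done + err_step}: pair-list buffer overflow")
        done += seg
        conf.time += seg * dt
        times.append(conf.time)
        energies.append(total_e())
    return np.asarray(times), np.asarray(energies), conf
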