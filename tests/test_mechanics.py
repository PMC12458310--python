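"""Force field: closed-form term values, gradient consistency, symmetries."""
import numpy as np
import pytest

from neuritesim import SimulationConfig
from neuritesim.cell_builder import (
    AreaGroup,
    AttractionRule,
    Configuration,
    Role,
    Topology,
)
from neuritesim.mechanics import (
    area_energy,
    attraction_energy,
    bend_energy,
    compute_forces,
    repulsion_energy,
    stretch_energy,
    total_energy,
)

WCA_CUT = 2.0 ** (1.0 / 6.0)
LJ_SHIFT_PER_EPS = -4.0 * ((1 / 2.5) ** 12 - (1 / 2.5) ** 6)  # -LJ(2.5)/eps


@pytest.mark.parametrize(
    "r, kappa, r0, expected",
    [(1.0, 10.0, 1.0, 0.0), (2.0, 10.0, 1.0, 5.0), (1.5, 500.0, 1.0, 62.5)],
)
def test_stretch_energy_closed_form(r, kappa, r0, expected):
    assert stretch_energy(r, kappa, r0) == pytest.approx(expected)


@pytest.mark.parametrize(
    "theta, expected", [(np.pi, 0.0), (np.pi / 2, 5.0), (0.0, 10.0)]
)
def test_bend_energy_straight_chain_form(theta, expected):
    assert bend_energy(theta, 5.0) == pytest.approx(expected, abs=1e-12)


def test_bend_energy_spontaneous_angle_vanishes_at_rest():
    theta0 = np.pi - 2 * np.pi / 240
    assert bend_energy(theta0, 5.0, theta0) == 0.0


@pytest.mark.parametrize(
    "r, u3, expected",
    [
        (2.5, 7.3, 0.0),  # cutoff
        (WCA_CUT, 3.0, -3.0 + 3.0 * LJ_SHIFT_PER_EPS),  # well bottom + shift
        (1.0, 1.0, 0.0 + 1.0 * LJ_SHIFT_PER_EPS),  # LJ zero crossing
    ],
)
def test_attraction_energy_truncated_shifted_lj(r, u3, expected):
    assert attraction_energy(r, u3, 1.0) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "r, eps, expected", [(WCA_CUT, 1.0, 0.0), (1.0, 1.0, 1.0), (3.0, 1.0, 0.0)]
)
def test_wca_repulsion_closed_form(r, eps, expected):
    assert repulsion_energy(r, eps, 1.0) == pytest.approx(expected, abs=1e-12)


def test_area_energy_closed_form_and_rigid_motion_invariance():
    square = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    # A=1, A0=0.5 -> 0.5 * 4 * 0.25 / 0.5 = 1.0
    assert area_energy(square, 4.0, 0.5) == pytest.approx(1.0)
    assert area_energy(square, 4.0, 1.0) == pytest.approx(0.0, abs=1e-14)
    ang = 0.5
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    moved = square @ rot.T + np.array([3.0, -7.0])
    assert area_energy(moved, 4.0, 0.5) == pytest.approx(1.0)


def _random_system(rng, n_beads):
    """A small system exercising every potential term at once."""
    # positions with a minimum separation to stay off force discontinuities
    pos = []
    while len(pos) < n_beads:
        p = rng.uniform(-4.0, 4.0, 2)
        if all(np.linalg.norm(p - q) > 0.85 for q in pos):
            pos.append(p)
    pos = np.array(pos)
    role = np.full(n_beads, int(Role.ACTIN), dtype=np.int8)
    role[: n_beads // 3] = int(Role.MEMBRANE)
    role[n_beads // 3] = int(Role.ACTIN_HEAD)

    idx = rng.permutation(n_beads)
    bonds = np.array([[idx[k], idx[k + 1]] for k in range(min(6, n_beads - 1))], dtype=np.int32)
    triples = np.array(
        [[idx[k], idx[k + 1], idx[k + 2]] for k in range(min(4, n_beads - 2))], dtype=np.int32
    )
    ring = np.sort(rng.choice(n_beads, size=5, replace=False)).astype(np.int32)
    topo = Topology(
        bonds=bonds,
        bond_kappa=rng.uniform(1.0, 50.0, len(bonds)),
        bond_r0=rng.uniform(0.5, 1.5, len(bonds)),
        triples=triples,
        triple_kappa=rng.uniform(1.0, 20.0, len(triples)),
        triple_phi0=rng.uniform(-0.3, 0.3, len(triples)),
        attraction=AttractionRule(u3=rng.uniform(0.5, 30.0), cutoff=2.5),
        area_groups=[AreaGroup(ring, 10.0, 3.0)],
    )
    conf = Configuration(
        positions=pos,
        velocities=np.zeros_like(pos),
        role=role,
        filament_id=np.full(n_beads, -1, dtype=np.int32),
    )
    return conf, topo


def _fd_max_rel_error(conf, topo, config, h=1e-6):
    forces, _ = compute_forces(conf, topo, config)
    worst = 0.0
    for i in range(conf.n_beads):
        for d in range(2):
            p = conf.copy()
            p.positions[i, d] += h
            ep = total_energy(p, topo, config)
            p.positions[i, d] -= 2 * h
            em = total_energy(p, topo, config)
            fd = -(ep - em) / (2 * h)
            worst = max(worst, abs(fd - forces[i, d]) / max(1.0, abs(fd)))
    return worst


def test_forces_match_finite_differences_on_random_systems():
    """Analytic forces = -grad E to 1e-6 across 100 random small systems."""
    rng = np.random.default_rng(12345)
    config = SimulationConfig()
    worst = 0.0
    for _ in range(100):
        conf, topo = _random_system(rng, int(rng.integers(8, 31)))
        worst = max(worst, _fd_max_rel_error(conf, topo, config))
    assert worst < 1e-6


def test_forces_on_built_cell_match_finite_differences(tiny_config):
    from neuritesim import build_cell

    conf, topo = build_cell(tiny_config)
    rng = np.random.default_rng(3)
    conf.positions += 0.05 * rng.standard_normal(conf.positions.shape)
    assert _fd_max_rel_error(conf, topo, tiny_config) < 1e-6


def test_net_force_and_torque_vanish(tiny_config):
    from neuritesim import build_cell

    conf, topo = build_cell(tiny_config)
    rng = np.random.default_rng(4)
    conf.positions += 0.05 * rng.standard_normal(conf.positions.shape)
    forces, e = compute_forces(conf, topo, tiny_config)
    assert np.abs(forces.sum(axis=0)).max() < 1e-9
    torque = float(np.sum(conf.positions[:, 0] * forces[:, 1] - conf.positions[:, 1] * forces[:, 0]))
    assert abs(torque) < 1e-8
    # energy breakdown closure
    parts = e.stretch + e.bend + e.attraction + e.repulsion + e.area
    assert e.total == pytest.approx(parts, rel=1e-12)


def test_bonded_pair_at_rest_length_feels_no_force():
    pos = np.array([[0.0, 0.0], [1.3, 0.0]])
    topo = Topology(
        bonds=np.array([[0, 1]], dtype=np.int32),
        bond_kappa=np.array([10.0]),
        bond_r0=np.array([1.3]),
        triples=np.zeros((0, 3), dtype=np.int32),
        triple_kappa=np.zeros(0),
        triple_phi0=np.zeros(0),
        attraction=AttractionRule(0.0, 2.5),
        area_groups=[],
    )
    conf = Configuration(
        positions=pos,
        velocities=np.zeros_like(pos),
        role=np.full(2, int(Role.ACTIN), dtype=np.int8),
        filament_id=np.full(2, -1, dtype=np.int32),
    )
    forces, e = compute_forces(conf, topo, SimulationConfig())
    assert np.abs(forces).max() == 0.0
    assert e.total == pytest.approx(0.0, abs=1e-14)
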