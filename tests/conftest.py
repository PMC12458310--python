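import numpy as np
import pytest

from neuritesim import SimulationConfig, build_cell
from neuritesim.cell_builder import Configuration, Role


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def default_cell(default_config):
    return build_cell(default_config)


@pytest.fixture()
def tiny_config():
    """A fast, valid cell: 60 + 20 + 4x6 = 104 beads."""
    return SimulationConfig(
        n_membrane=60,
        n_nucleus=20,
        n_filaments=4,
        beads_per_filament=6,
        r_cell=10.0,
        r_nucleus=3.0,
        n_steps=500,
        save_every=100,
        seed=1,
    )


def make_ring_frame(radii, n=None):
    """Membrane-only frame with prescribed per-bead radial distances."""
    radii = np.asarray(radii, dtype=float)
    n = len(radii) if n is None else n
    angles = 2.0 * np.pi * np.arange(n) / n
    pos = np.stack([radii * np.cos(angles), radii * np.sin(angles)], axis=1)
    return Configuration(
        positions=pos,
        velocities=np.zeros_like(pos),
        role=np.full(n, int(Role.MEMBRANE), dtype=np.int8),
        filament_id=np.full(n, -1, dtype=np.int32),
        time=0.0,
    )


@pytest.fixture()
def ring_frame_factory():
    return make_ring_frame
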