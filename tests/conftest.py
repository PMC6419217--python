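import numpy as np
import pytest

from nanothz.trajectory import Frame, Topology, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_trajectory(
    n_frames=5,
    n_atoms=10,
    dt=0.1,
    box=(12.0, 12.0, 12.0),
    velocities=False,
    seed=123,
):
    """Random in-box trajectory for I/O and estimator tests."""
    r = np.random.default_rng(seed)
    frames = []
    for i in range(n_frames):
        pos = r.uniform(0, np.min(box), size=(n_atoms, 3))
        vel = r.normal(0, 1.0, size=(n_atoms, 3)) if velocities else None
        frames.append(Frame(time=i * dt, box=box, positions=pos, velocities=vel))
    elements = ["C"] * n_atoms
    return Trajectory(frames, elements=elements)


def water_topology():
    """Single TIP3P-like water: O is donor+acceptor with two hydrogens."""
    return Topology(
        name=["O", "H1", "H2"],
        element=["O", "H", "H"],
        mass=np.array([15.9994, 1.008, 1.008]),
        charge=np.array([-0.834, 0.417, 0.417]),
        mol_id=np.array([0, 0, 0]),
        hbond_role=["both", "hydrogen", "hydrogen"],
        bonded_hydrogens=[[1, 2], [], []],
    )
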