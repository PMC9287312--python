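import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from siescore.structio import AtomRecord, MolecularSystem, Selection
from siescore.synthdata import SyntheticSpec, make_pseudo_trajectory, make_toy_complex


@pytest.fixture(scope="session")
def spec():
    return SyntheticSpec()


@pytest.fixture(scope="session")
def complex_system(spec):
    return make_toy_complex(spec)


@pytest.fixture(scope="session")
def neutral_system():
    return make_toy_complex(SyntheticSpec(charge_model="zero-net"))


@pytest.fixture(scope="session")
def short_traj(complex_system):
    return make_pseudo_trajectory(complex_system, SyntheticSpec(n_frames=6, seed=7))


def make_random_groups(rng, n_a=10, n_b=10, charged=True):
    """Two well-separated random atom groups with full parameters."""
    atoms = []
    for i in range(n_a):
        xyz = rng.uniform(0.0, 5.0, 3)
        atoms.append(AtomRecord(i + 1, f"A{i}", "C", "GRP", 1, "A", xyz,
                                charge=rng.uniform(-1, 1) if charged else 0.0,
                                lj_epsilon=rng.uniform(0.01, 0.3),
                                lj_rmin_half=rng.uniform(1.2, 2.0),
                                radius=rng.uniform(1.2, 2.0)))
    for j in range(n_b):
        xyz = rng.uniform(0.0, 5.0, 3) + np.array([8.0, 0.0, 0.0])
        atoms.append(AtomRecord(n_a + j + 1, f"B{j}", "O", "GRP", 2, "B", xyz,
                                charge=rng.uniform(-1, 1) if charged else 0.0,
                                lj_epsilon=rng.uniform(0.01, 0.3),
                                lj_rmin_half=rng.uniform(1.2, 2.0),
                                radius=rng.uniform(1.2, 2.0)))
    system = MolecularSystem(atoms)
    sel_a = Selection(tuple(range(n_a)), "A")
    sel_b = Selection(tuple(range(n_a, n_a + n_b)), "B")
    system.set_partition(sel_a, sel_b)
    return system, sel_a, sel_b


def random_rigid_motion(rng):
    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.uniform(-20, 20, 3)
    return lambda xyz: xyz @ rot.T + trans
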