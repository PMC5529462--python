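import numpy as np
import pytest

from serpinflex import synthetic
from serpinflex.traj_io import Atom, Structure, Trajectory


@pytest.fixture(scope="session")
def toy_chain():
    """60-residue backbone chain: helix, coil, hairpin, coil."""
    return synthetic.build_toy_chain(60)


@pytest.fixture(scope="session")
def toy_ca_chain():
    return synthetic.build_toy_chain(50, ca_only=True)


def make_ca_structure(coords, start_res=1, chain="A"):
    """CA-only structure from an (n, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    atoms = [
        Atom(i + 1, "CA", "C", "ALA", start_res + i, chain, coords[i])
        for i in range(coords.shape[0])
    ]
    return Structure(atoms)


def make_trajectory(frames, start_res=1, frame_interval=2.0):
    """CA-only trajectory from an (n_frames, n_atoms, 3) array."""
    frames = np.asarray(frames, dtype=float)
    top = make_ca_structure(frames[0], start_res=start_res)
    return Trajectory(top, frames, frame_interval)


def random_rigid_transform(rng):
    from scipy.spatial.transform import Rotation

    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    return R, t
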