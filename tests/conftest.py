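import numpy as np
import pandas as pd
import pytest

from myoadp.trajectory import Trajectory


def make_topology(n_atoms, resids, elements=None, names=None, charges=None,
                  sigma=3.0, epsilon=0.1, masses=None):
    elements = elements or ["C"] * n_atoms
    names = names or [f"X{i}" for i in range(n_atoms)]
    return pd.DataFrame({
        "name": names,
        "element": elements,
        "resid": resids,
        "resname": ["RES"] * n_atoms,
        "mass": masses if masses is not None else [12.0] * n_atoms,
        "charge": charges if charges is not None else [0.0] * n_atoms,
        "sigma": [sigma] * n_atoms,
        "epsilon": [epsilon] * n_atoms,
    })


@pytest.fixture
def random_trajectory():
    """Small random-coordinate trajectory (12 atoms / 3 residues / 25 frames)
    with nonzero charges, for brute-force oracle comparisons."""
    rng = np.random.default_rng(42)
    n_atoms, n_frames = 12, 25
    resids = np.repeat([0, 1, 2], 4)
    charges = rng.uniform(-0.8, 0.8, n_atoms)
    top = make_topology(n_atoms, resids, charges=charges,
                        masses=rng.uniform(1.0, 16.0, n_atoms))
    coords = rng.uniform(0.0, 12.0, size=(n_frames, n_atoms, 3))
    return Trajectory(coords=coords, topology=top)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
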