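import numpy as np
import pandas as pd
import pytest

from lipidobs.core_io import Topology, Trajectory
from lipidobs import synthetic


@pytest.fixture
def small_topology():
    """Three-atom mixed system: one peptide N, one lipid P, one water O."""
    atoms = pd.DataFrame([
        dict(atom_id=0, name="N", atomic_number=7, residue_name="R",
             residue_index=19, molecule_id=1, species="PEPTIDE", charge=0.5,
             lj_sigma=0.33, lj_epsilon=0.7, mass=14.0, leaflet="none"),
        dict(atom_id=1, name="P", atomic_number=15, residue_name="MAIPG",
             residue_index=1, molecule_id=2, species="MAIPG", charge=-1.0,
             lj_sigma=0.37, lj_epsilon=0.6, mass=31.0, leaflet="upper"),
        dict(atom_id=2, name="OW", atomic_number=8, residue_name="SOL",
             residue_index=2, molecule_id=3, species="WATER", charge=-0.8,
             lj_sigma=0.32, lj_epsilon=0.65, mass=16.0, leaflet="none"),
    ])
    return Topology(atoms)


@pytest.fixture
def small_trajectory(small_topology):
    rng = np.random.default_rng(7)
    n_frames, n_atoms = 3, small_topology.n_atoms
    coords = rng.uniform(0.5, 4.5, size=(n_frames, n_atoms, 3))
    boxes = np.full((n_frames, 3), 5.0)
    return Trajectory(np.arange(n_frames, dtype=float), boxes, coords)


@pytest.fixture
def composition_fixture():
    return synthetic.membrane_composition_fixture()
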