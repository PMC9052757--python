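import numpy as np
import pytest

from allostate import synthdata
from allostate.trajio import Atom, StructureModel, TrajectoryEnsemble


@pytest.fixture(scope="session")
def triple_well():
    """The calibrated three-basin potential (dense refinement is cached)."""
    return synthdata.make_triple_well()


@pytest.fixture(scope="session")
def coarse_triple_well():
    """Faster 2°-grid variant for tests that only need the analytic form."""
    return synthdata.make_triple_well(grid_resolution=2.0)


def make_structure(n_residues=3, chain="A", spacing=3.8):
    """A minimal poly-ALA Cα+backbone structure for geometry tests."""
    atoms, coords = [], []
    for i in range(n_residues):
        x = i * spacing
        for name, offset in (("N", (0.0, 0.0, 0.0)),
                             ("CA", (0.8, 1.0, 0.0)),
                             ("C", (1.9, 0.3, 0.4))):
            atoms.append(Atom(name=name, resid=str(i + 1), resname="ALA",
                              chain=chain, element=name[0]))
            coords.append((x + offset[0], offset[1], offset[2]))
    return StructureModel(atoms=atoms, coordinates=np.array(coords))


def make_trajectory(frames, topology=None, times=None):
    frames = np.asarray(frames, dtype=float)
    if topology is None:
        n_atoms = frames.shape[1]
        atoms = [Atom(name=f"X{i}", resid=str(i + 1), resname="UNK",
                      chain="A", element="C") for i in range(n_atoms)]
        topology = StructureModel(atoms=atoms, coordinates=frames[0])
    if times is None:
        times = np.arange(len(frames), dtype=float)
    return TrajectoryEnsemble(frames=frames, times=times, topology=topology)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
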