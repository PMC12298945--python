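import numpy as np
import pytest

from gbind.core import AtomRecord, Frame, Selection, Topology
from gbind.synthetic import ToyComplexSpec, build_toy_complex

#: jitter scale (Å) for energy-analysis ensembles: i.i.d. noise maps
#: one-to-one onto relative contact-distance noise, so it is kept well
#: below the Lennard-Jones wall scale of the 1.8 Å hydrogen-bond contact
ENERGY_SIGMA = 0.04


def make_atom(index, *, name="C", element="C", residue_index=0,
              residue_name="LEU", segment="receptor", charge=0.0,
              lj_rmin_half=1.9, lj_epsilon=0.1, gb_radius=1.6,
              gb_screen=0.8, mass=12.0):
    return AtomRecord(index=index, name=name, element=element,
                      residue_index=residue_index, residue_name=residue_name,
                      segment=segment, charge=charge,
                      lj_rmin_half=lj_rmin_half, lj_epsilon=lj_epsilon,
                      gb_radius=gb_radius, gb_screen=gb_screen, mass=mass)


def topology_from(coords, **common):
    """Topology of bare carbon-like atoms, one residue each."""
    atoms = tuple(
        make_atom(i, residue_index=i, **common) for i in range(len(coords))
    )
    return Topology(atoms=atoms), Frame(coordinates=np.asarray(coords, float))


@pytest.fixture(scope="session")
def toy_complex():
    """8-residue receptor with one planted hydrogen bond (residue 6)."""
    spec = ToyComplexSpec(n_receptor_residues=8, ligand_atoms=6,
                          hbond_pairs=((6, 0),), seed=1)
    return build_toy_complex(spec)


@pytest.fixture
def full_selection():
    def _make(topology):
        return Selection(atom_indices=tuple(range(topology.n_atoms)),
                         label="all")
    return _make
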