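import numpy as np
import pytest

from allostat.structure_io import AnnotatedStructure, AtomRecord, Region
from allostat.synthetic_data import build_reference_complex


@pytest.fixture(scope="session")
def reference():
    """The deterministic toy reader/enzyme/ligand complex."""
    return build_reference_complex()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_structure(coords, chain="A", resnums=None, names=None, elements=None,
                   resname="ALA", regions=None):
    """Small helper: structure from a coordinate array with default labels."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    resnums = resnums if resnums is not None else list(range(1, n + 1))
    names = names if names is not None else [f"X{i+1}" for i in range(n)]
    elements = elements if elements is not None else ["C"] * n
    atoms = [
        AtomRecord(names[i], elements[i], chain, resnums[i], resname, tuple(coords[i]))
        for i in range(n)
    ]
    return AnnotatedStructure(atoms, regions or {})


@pytest.fixture
def tri_residue():
    """One 10-atom residue with 4 hydrogens, for selection-filter counting."""
    names = ["N", "CA", "C", "O", "CB", "CG", "H", "HA", "HB1", "HB2"]
    elements = ["N", "C", "C", "O", "C", "C", "H", "H", "H", "H"]
    coords = np.arange(30, dtype=float).reshape(10, 3) / 10.0
    return make_structure(coords, resnums=[5] * 10, names=names, elements=elements)
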