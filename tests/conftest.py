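import numpy as np
import pytest

from ribodyn.peakio import Atom, ResidueID, StructureModel


@pytest.fixture
def five_atom_pdb(tmp_path):
    """Hand-written minimal PDB with exactly 5 atoms."""
    text = """\
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.500   2.000   3.000  1.00  0.00           C
ATOM      3  C   ALA A   1       3.200   3.300   3.000  1.00  0.00           C
ATOM      4  O   ALA A   1       3.200   4.500   3.000  1.00  0.00           O
ATOM      5  N   GLY A   2       4.400   2.900   3.100  1.00  0.00           N
END
"""
    path = tmp_path / "five.pdb"
    path.write_text(text)
    return path


@pytest.fixture
def tiny_structure():
    return StructureModel(atoms=[
        Atom("N", ResidueID(1, "ALA"), "N", (0.0, 0.0, 0.0)),
        Atom("CA", ResidueID(1, "ALA"), "C", (1.5, 0.0, 0.0)),
        Atom("C", ResidueID(1, "ALA"), "C", (2.2, 1.3, 0.0)),
        Atom("O", ResidueID(1, "ALA"), "O", (2.2, 2.5, 0.0)),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
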