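import numpy as np
import pytest

from hydromoment.sasa import reference_asa_table
from hydromoment.structure import assign_radii_and_charges, build_extended_tripeptide
from hydromoment.synthetic import GlobuleSpec, make_globule

# Minimal hand-written 3-residue PDB (Ala-Gly-Ser) used for parser tests.
MINI_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       2.000  -0.900   1.200  1.00  0.00           C
ATOM      6  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      7  CA  GLY A   2       3.934   2.866   0.000  1.00  0.00           C
ATOM      8  C   GLY A   2       5.450   2.750   0.000  1.00  0.00           C
ATOM      9  O   GLY A   2       6.030   1.660   0.000  1.00  0.00           O
ATOM     10  N   SER A   3       6.100   3.910   0.000  1.00  0.00           N
ATOM     11  CA  SER A   3       7.550   3.950   0.000  1.00  0.00           C
ATOM     12  C   SER A   3       8.110   5.370   0.000  1.00  0.00           C
ATOM     13  O   SER A   3       7.370   6.360   0.000  1.00  0.00           O
ATOM     14  CB  SER A   3       8.100   3.200   1.210  1.00  0.00           C
ATOM     15  OG  SER A   3       7.680   1.850   1.250  1.00  0.00           O
TER
END
"""

WATER_LINE = (
    "HETATM   16  O   HOH A 101      10.000  10.000  10.000"
    "  1.00  0.00           O\n"
)


@pytest.fixture
def mini_pdb(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(MINI_PDB)
    return path


@pytest.fixture
def mini_pdb_with_water(tmp_path):
    path = tmp_path / "mini_water.pdb"
    path.write_text(MINI_PDB.replace("TER\n", "TER\n" + WATER_LINE))
    return path


@pytest.fixture(scope="session")
def ala_tripeptide():
    return assign_radii_and_charges(build_extended_tripeptide("ALA"))


@pytest.fixture(scope="session")
def computed_reference():
    """Self-computed extended Gly-X-Gly reference ASA at default settings
    (shared across tests; the computation itself is what several tests
    check)."""
    return reference_asa_table()


@pytest.fixture(scope="session")
def globule100():
    """A compact spherical synthetic globule, parameters assigned."""
    return make_globule(GlobuleSpec(n_residues=100, seed=11))


def dihedral(p0, p1, p2, p3):
    """Dihedral angle in degrees (test-local reference implementation)."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    return np.degrees(np.arctan2(np.dot(np.cross(b1, v), w), np.dot(v, w)))
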