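import numpy as np
import pytest

from iondist import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


#: Minimal hand-written PDB text: one alanine (5 heavy atoms, one with a
#: hydrogen that must be dropped) and one zinc ion 3 A from the residue's
#: geometry center region.
ALA_ZN_PDB = """\
ATOM      1  N   ALA A   1       1.458   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C
ATOM      3  C   ALA A   1      -0.521   1.432   0.000  1.00 10.00           C
ATOM      4  O   ALA A   1      -1.680   1.755   0.250  1.00 10.00           O
ATOM      5  CB  ALA A   1      -0.540   -0.81   -1.08  1.00 10.00           C
ATOM      6  HB1 ALA A   1      -0.100  -1.700  -1.500  1.00 10.00           H
HETATM    7 ZN    ZN A 101       2.000   2.000   1.500  1.00 20.00          ZN
END
"""

WATER_RECORDS = """\
HETATM    8  O   HOH A 201      10.000  10.000  10.000  1.00 30.00           O
HETATM    9  O   HOH A 202      11.000  10.000  10.000  1.00 30.00           O
HETATM   10  O   HOH A 203      12.000  10.000  10.000  1.00 30.00           O
"""

#: Alanine whose CB carries two alternate locations with different
#: occupancies (A: 0.6 at one position, B: 0.4 elsewhere).
ALA_ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       1.458   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C
ATOM      3  C   ALA A   1      -0.521   1.432   0.000  1.00 10.00           C
ATOM      4  O   ALA A   1      -1.680   1.755   0.250  1.00 10.00           O
ATOM      5  CB AALA A   1      -0.540  -0.810  -1.080  0.60 10.00           C
ATOM      6  CB BALA A   1      -0.500  -0.900  -1.000  0.40 10.00           C
END
"""


@pytest.fixture
def ala_zn_pdb():
    return ALA_ZN_PDB


@pytest.fixture
def ala_zn_waters_pdb():
    return ALA_ZN_PDB.replace("END\n", "") + WATER_RECORDS + "END\n"


@pytest.fixture
def ala_altloc_pdb():
    return ALA_ALTLOC_PDB


@pytest.fixture
def small_statsdb(rng):
    """StatsDB accumulated from a handful of random synthetic fixtures."""
    from iondist import accumulate, parse_structure

    structures = []
    for _ in range(6):
        spec = syn.random_fixture(rng, n_residues=4, n_ions=4,
                                  octant_margin=0.05)
        structures.append(
            parse_structure(syn.make_pdb_fixture(spec), spec.source_id)
        )
    return accumulate(structures)
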