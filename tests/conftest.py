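import numpy as np
import pytest

from aldpkit.structure_model import (
    AtomRecord,
    Residue,
    ResidueRef,
    StructureModel,
)

TINY_PDB = """\
ATOM      1  N   ALA A   1       0.000   1.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   1.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   2.400   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.300   3.400   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       2.000   0.200   1.200  1.00  0.00           C
ATOM      6  N   GLY A   2       3.300   2.500   0.000  1.00  0.00           N
ATOM      7  CA  GLY A   2       4.000   3.800   0.000  1.00  0.00           C
ATOM      8  C   GLY A   2       5.500   3.600   0.000  1.00  0.00           C
ATOM      9  O   GLY A   2       6.100   2.500   0.000  1.00  0.00           O
ATOM     10  N   SER A   3       6.200   4.700   0.000  1.00  0.00           N
ATOM     11  CA  SER A   3       7.650   4.700   0.000  1.00  0.00           C
ATOM     12  C   SER A   3       8.200   6.100   0.000  1.00  0.00           C
ATOM     13  O   SER A   3       7.500   7.100   0.000  1.00  0.00           O
ATOM     14  OG  SER A   3       8.300   3.900   1.100  1.00  0.00           O
TER      15
HETATM   16  C1  LIG A 101      10.000  10.000  10.000  1.00  0.00           C
HETATM   17  C2  LIG A 101      11.000  10.000  10.000  1.00  0.00           C
HETATM   18  O1  LIG A 101      12.000  10.000  10.000  1.00  0.00           O
HETATM   19  C3  LIG A 101      13.000  10.000  10.000  1.00  0.00           C
HETATM   20  C4  LIG A 101      14.000  10.000  10.000  1.00  0.00           C
HETATM   21  O   HOH A 201      20.000  20.000  20.000  1.00  0.00           O
END
"""


@pytest.fixture
def tiny_pdb_text() -> str:
    return TINY_PDB


def ca_model(coords, chain="A", start=1, entry_id="TEST") -> StructureModel:
    """CA-only model from an (N, 3) array, residues numbered from ``start``."""
    residues = []
    for i, xyz in enumerate(np.asarray(coords, dtype=float)):
        ref = ResidueRef(chain, start + i, "", "A")
        residues.append(
            Residue(ref=ref, name="ALA", atoms=[AtomRecord("CA", "C", xyz)])
        )
    return StructureModel(entry_id=entry_id, chains={chain: residues})


def make_residue(chain, num, name, atom_spec) -> Residue:
    """Residue from [(atom_name, element, xyz), ...]."""
    atoms = [AtomRecord(a, el, np.asarray(xyz, float)) for a, el, xyz in atom_spec]
    from aldpkit.structure_model import THREE_TO_ONE

    return Residue(
        ref=ResidueRef(chain, num, "", THREE_TO_ONE.get(name, name)),
        name=name,
        atoms=atoms,
    )
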