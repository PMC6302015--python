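from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ionbind.structure import AtomRecord, ProteinStructure

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_atom(name: str, pos, residue: str = "ASP", seq: int = 1,
              chain: str = "A", element: str | None = None, serial: int = 1,
              het: bool = False, occ: float = 1.0, alt: str = "") -> AtomRecord:
    """Shorthand AtomRecord constructor for in-memory test structures."""
    if element is None:
        element = name[0]
    return AtomRecord(serial=serial, atom_name=name, residue_name=residue,
                      chain_id=chain, residue_seq=seq, alt_loc=alt,
                      occupancy=occ, position=np.asarray(pos, dtype=float),
                      element=element, is_hetero=het)


def make_structure(atoms, identifier="test") -> ProteinStructure:
    # distinct residue_seq per atom unless caller set them
    fixed = []
    seen = set()
    for i, a in enumerate(atoms):
        key = a.site_key
        if key in seen:
            a = make_atom(a.atom_name, a.position, residue=a.residue_name,
                          seq=1000 + i, chain=a.chain_id, element=a.element,
                          serial=a.serial, het=a.is_hetero, occ=a.occupancy)
        seen.add(a.site_key)
        fixed.append(a)
    return ProteinStructure(fixed, identifier=identifier)


TETRAHEDRON = np.array([[1.0, 1.0, 1.0], [1.0, -1.0, -1.0],
                        [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]) / np.sqrt(3.0)


@pytest.fixture
def tetra_site_structure():
    """Four carboxylate oxygens at 2.0 A from the origin, tetrahedral."""
    atoms = [make_atom("OD1", 2.0 * d, seq=i + 1, serial=i + 1)
             for i, d in enumerate(TETRAHEDRON)]
    return ProteinStructure(atoms, identifier="tetra")


TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       1.986  -0.760  -1.220  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BALA A   1       0.500   0.000   0.000  0.40  0.00           C
ATOM      3  CB AALA A   1       1.000   0.000   0.000  0.50  0.00           C
ATOM      4  CB BALA A   1       1.500   0.000   0.000  0.50  0.00           C
END
"""

MIXED_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  HA  ALA A   1       0.500   0.500   0.000  1.00  0.00           H
ATOM      3  OD1 ASP B   2       3.000   0.000   0.000  1.00  0.00           O
HETATM    4 ZN    ZN A 101       5.000   5.000   5.000  1.00  0.00          ZN
HETATM    5  O   HOH A 201       7.000   7.000   7.000  1.00  0.00           O
END
"""


@pytest.fixture
def toy_pdb_file(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    return p


@pytest.fixture
def altloc_pdb_file(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p


@pytest.fixture
def mixed_pdb_file(tmp_path):
    p = tmp_path / "mixed.pdb"
    p.write_text(MIXED_PDB)
    return p
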