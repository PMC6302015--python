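"""Reading protein structures into flat heavy-atom records.

The site-prediction geometry only needs atom names, residue typing and
coordinates, so structures are flattened into a list of :class:`AtomRecord`.
Parsing of PDB/mmCIF is delegated to gemmi; this module applies the
conventions used throughout the package: hydrogens dropped, alternate
locations resolved to the highest-occupancy conformer, waters excluded
unless requested, heteroatom metals retained but flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np

STANDARD_AA = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
})

WATER_RESIDUES = frozenset({"HOH", "WAT", "DOD", "H2O"})


class StructureError(ValueError):
    """Base class for structure-input problems."""


class StructureFormatError(StructureError):
    """The file could not be parsed as PDB or mmCIF."""


class EmptyStructureError(StructureError):
    """The selection retained no atoms."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom with PDB-style typing.

    ``atom_name`` follows the PDB convention ("OD1", "SG", backbone "O"),
    ``position`` is in Angstroms in the file's native frame.
    """

    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_seq: int
    alt_loc: str
    occupancy: float
    position: np.ndarray
    element: str
    is_hetero: bool = False
    is_metal: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError("occupancy must lie in [0, 1]")
        if not self.element:
            raise ValueError("element must be non-empty")

    @property
    def site_key(self) -> tuple[str, int, str]:
        """Identity of the atom site, ignoring alternate conformers."""
        return (self.chain_id, self.residue_seq, self.atom_name)

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_RESIDUES


@dataclass
class ProteinStructure:
    """A set of retained heavy atoms from one model of a structure file."""

    atoms: list[AtomRecord]
    identifier: str = ""
    resolution_note: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyStructureError("structure contains no atoms")
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            if a.site_key in seen:
                raise ValueError(f"duplicate atom site {a.site_key} after alt-loc resolution")
            seen.add(a.site_key)

    def __len__(self) -> int:
        return len(self.atoms)

    def positions(self) -> np.ndarray:
        """(n, 3) array of atom coordinates in file order."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProteinStructure":
        """Return a copy with every atom moved by ``R x + t`` (rigid motion)."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        moved = [
            AtomRecord(
                serial=a.serial, atom_name=a.atom_name, residue_name=a.residue_name,
                chain_id=a.chain_id, residue_seq=a.residue_seq, alt_loc=a.alt_loc,
                occupancy=a.occupancy, position=R @ a.position + t, element=a.element,
                is_hetero=a.is_hetero, is_metal=a.is_metal,
            )
            for a in self.atoms
        ]
        return ProteinStructure(moved, identifier=self.identifier,
                                resolution_note=self.resolution_note)


def _resolve_alt_locs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    # Highest occupancy wins; ties go to the alphabetically first alt_loc.
    best: dict[tuple[str, int, str], AtomRecord] = {}
    order: list[tuple[str, int, str]] = []
    for a in atoms:
        key = a.site_key
        if key not in best:
            best[key] = a
            order.append(key)
        else:
            b = best[key]
            if (a.occupancy > b.occupancy
                    or (a.occupancy == b.occupancy and a.alt_loc < b.alt_loc)):
                best[key] = a
    return [best[k] for k in order]


def load_structure(path: str | Path, chain_filter: Optional[str] = None,
                   include_waters: bool = False) -> ProteinStructure:
    """Load a PDB or mmCIF file into a :class:`ProteinStructure`.

    Hydrogens are dropped, alternate-location groups keep only the
    highest-occupancy conformer (ties broken by the alphabetically first
    alt-loc), waters are dropped unless ``include_waters`` is set, and
    heteroatom metals are retained with ``is_metal`` set.

    Raises :class:`StructureFormatError` for unparseable input and
    :class:`EmptyStructureError` when the selection retains nothing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path} contains no model")

    records: list[AtomRecord] = []
    model = st[0]
    for chain in model:
        if chain_filter is not None and chain.name != chain_filter:
            continue
        for res in chain:
            water = res.is_water() or res.name in WATER_RESIDUES
            if water and not include_waters:
                continue
            het = res.het_flag == "H"
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                records.append(AtomRecord(
                    serial=atom.serial,
                    atom_name=atom.name,
                    residue_name=res.name,
                    chain_id=chain.name,
                    residue_seq=res.seqid.num,
                    alt_loc=atom.altloc or "",
                    occupancy=min(max(atom.occ, 0.0), 1.0),
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    element=atom.element.name,
                    is_hetero=het,
                    is_metal=atom.element.is_metal,
                ))

    records = _resolve_alt_locs(records)
    if not records:
        raise EmptyStructureError(f"no atoms retained from {path}"
                                  + (f" (chain {chain_filter})" if chain_filter else ""))
    note = None
    if st.resolution:
        note = f"{st.resolution:.2f} A"
    return ProteinStructure(records, identifier=st.name or path.stem, resolution_note=note)
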