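"""Reading protein structures and writing local-frame point clouds.

Structures arrive as PDB-format text.  Parsing reduces each file to the
two object kinds the analysis needs: amino-acid residues (heavy atoms
only, canonical 20 types) and monoatomic ion sites drawn from a curated
table of chemical-component names.  Waters, polyatomic hetero groups,
hydrogens and non-canonical residues are dropped; alternate locations
are resolved to the highest-occupancy conformer.

The point-cloud writer emits the analysis' export dialect: one
HETATM-style record per ion in a residue's local frame, with the source
structure id in the atom-name/segment fields, the source chain in the
chain-id column and the distance to the residue geometry center in the
B-factor column.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: The 20 proteinogenic amino acids, three-letter codes.
CANONICAL_AA: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

#: Curated monoatomic-ion table: PDB chemical-component name -> canonical
#: ion label.  Ferrous and ferric iron are pooled into one label because
#: crystallographic assignment of the iron oxidation state is unreliable.
#: The component name "CA" (calcium ion) never collides with the
#: alpha-carbon atom: ions are identified by residue name on single-atom
#: HETATM groups, not by atom name.
ION_TABLE: dict[str, str] = {
    "LI": "Li+",
    "NA": "Na+",
    "K": "K+",
    "RB": "Rb+",
    "CS": "Cs+",
    "MG": "Mg2+",
    "CA": "Ca2+",
    "SR": "Sr2+",
    "BA": "Ba2+",
    "MN": "Mn2+",
    "FE": "Fe2+/3+",
    "FE2": "Fe2+/3+",
    "CO": "Co2+",
    "NI": "Ni2+",
    "CU": "Cu2+",
    "CU1": "Cu+",
    "ZN": "Zn2+",
    "CD": "Cd2+",
    "HG": "Hg2+",
    "F": "F-",
    "CL": "Cl-",
    "BR": "Br-",
    "IOD": "I-",
}

_WATER_NAMES = {"HOH", "DOD", "WAT", "H2O"}


@dataclass
class Atom:
    """One heavy atom: name, element symbol and position in angstroms."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    alt_loc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not self.element:
            raise ValueError("atom element must be non-empty")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    """One amino acid: canonical type, chain/sequence identity, heavy atoms."""

    aa_type: str
    chain_id: str
    seq_id: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.aa_type not in CANONICAL_AA:
            raise ValueError(f"{self.aa_type!r} is not a canonical amino acid")

    def atom_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class IonSite:
    """One monoatomic ion site."""

    ion_type: str
    element: str
    coords: np.ndarray
    source_id: str = ""
    chain_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.ion_type not in set(ION_TABLE.values()):
            raise ValueError(f"unknown ion label {self.ion_type!r}")


@dataclass
class Structure:
    """Residues and ion sites of one model of one structure file."""

    source_id: str
    residues: list[Residue] = field(default_factory=list)
    ions: list[IonSite] = field(default_factory=list)


def _resolve_altlocs(atoms: Sequence[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties broken by
    lexicographically smallest altLoc indicator."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    kept = []
    for name in order:
        group = by_name[name]
        kept.append(min(group, key=lambda a: (-a.occupancy, a.alt_loc)))
    return kept


def _is_hydrogen(element: str) -> bool:
    return element.upper() in ("H", "D", "T")


def parse_structure(pdb_text: str, source_id: str = "") -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Only the first model of multi-model files is used.  Hydrogens are
    dropped, alternate locations resolved to the highest-occupancy copy,
    waters and polyatomic hetero groups excluded, and residues with
    non-canonical names skipped (with a log entry).  Monoatomic hetero
    groups whose component name is not in :data:`ION_TABLE` are logged
    and excluded.

    A file with no usable residue yields an empty Structure, not an
    error.
    """
    st = gemmi.read_pdb_string(pdb_text)
    out = Structure(source_id=source_id or st.name or "unknown")
    if len(st) == 0:
        return out
    model = st[0]
    for chain in model:
        for res in chain:
            name = res.name.strip()
            atoms = []
            for at in res:
                elem = at.element.name
                if _is_hydrogen(elem):
                    continue
                alt = at.altloc if at.altloc and at.altloc != "\x00" else ""
                atoms.append(
                    Atom(
                        name=at.name,
                        element=elem,
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=at.occ,
                        alt_loc=alt,
                    )
                )
            atoms = _resolve_altlocs(atoms)
            if not atoms:
                continue
            if name in CANONICAL_AA:
                out.residues.append(
                    Residue(
                        aa_type=name,
                        chain_id=chain.name,
                        seq_id=res.seqid.num,
                        icode=(res.seqid.icode or "").strip(),
                        atoms=atoms,
                    )
                )
            elif name in _WATER_NAMES:
                continue
            elif len(atoms) == 1 and name in ION_TABLE:
                out.ions.append(
                    IonSite(
                        ion_type=ION_TABLE[name],
                        element=atoms[0].element,
                        coords=atoms[0].coords,
                        source_id=out.source_id,
                        chain_id=chain.name,
                    )
                )
            elif len(atoms) == 1:
                logger.info(
                    "%s: unknown monoatomic hetero species %r skipped",
                    out.source_id, name,
                )
            else:
                logger.info(
                    "%s: non-canonical residue / polyatomic hetero group %r "
                    "skipped", out.source_id, name,
                )
    return out


def _pdb_atom_name_field(name: str) -> str:
    """Fixed-column atom-name field (cols 13-16): names up to 3 chars start
    in column 14 unless the element symbol takes two characters."""
    name = name[:4]
    if len(name) < 4:
        return f" {name:<3s}"
    return name


def write_point_cloud(pairs: Iterable["object"]) -> str:
    """Render pair records of one (amino acid, ion) combination as a
    PDB-format point cloud.

    One HETATM record per ion: coordinates are the local-frame Cartesian
    coordinates, the B-factor column holds the distance to the residue
    geometry center (two decimals), the chain-id column the source chain
    and the atom-name plus segment fields the source structure id.
    """
    pairs = list(pairs)
    lines = ["REMARK   3 ION POINT CLOUD IN RESIDUE-LOCAL COORDINATES"]
    if pairs:
        key = (pairs[0].aa_type, pairs[0].ion_type)
        for p in pairs:
            if (p.aa_type, p.ion_type) != key:
                raise ValueError(
                    f"mixed pair types: expected {key}, got "
                    f"({p.aa_type}, {p.ion_type}) from {p.source_id}"
                )
        lines.append(f"REMARK   3 AMINO ACID {key[0]}  ION {key[1]}")
    serial = 0
    for p in pairs:
        serial += 1
        x, y, z = p.local.cart
        elem = _ion_element(p.ion_type)
        name_field = _pdb_atom_name_field(p.source_id[:4].upper() or elem)
        chain = (p.chain_id or "A")[:1]
        seg = f"{p.source_id[:4]:<4s}"
        lines.append(
            f"HETATM{serial:5d} {name_field} ION {chain}{serial % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{p.gc_distance:6.2f}      "
            f"{seg}{elem:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def _ion_element(ion_type: str) -> str:
    for comp, label in ION_TABLE.items():
        if label == ion_type:
            sym = comp.capitalize()
            return {"Fe2": "Fe", "Cu1": "Cu", "Iod": "I"}.get(sym, sym)
    return "X"


def read_point_cloud(text: str) -> np.ndarray:
    """Read back the coordinates of a point-cloud file as an (n, 3) array."""
    coords = []
    for line in text.splitlines():
        if line.startswith(("HETATM", "ATOM")):
            coords.append(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            )
    return np.array(coords, dtype=float).reshape(-1, 3)


def structure_to_pdb(structure: Structure) -> str:
    """Write a :class:`Structure` back to minimal PDB-format text."""
    lines = []
    serial = 0
    for r in structure.residues:
        for a in r.atoms:
            serial += 1
            lines.append(_atom_line("ATOM", serial, a.name, r.aa_type,
                                    r.chain_id, r.seq_id, a.coords,
                                    a.occupancy, a.element))
    for ion in structure.ions:
        serial += 1
        comp = _component_name(ion.ion_type, ion.element)
        lines.append(_atom_line("HETATM", serial, ion.element.upper(), comp,
                                ion.chain_id or "A", serial, ion.coords,
                                1.0, ion.element))
    lines.append("END")
    return "\n".join(lines) + "\n"


def _component_name(ion_type: str, element: str) -> str:
    for comp, label in ION_TABLE.items():
        if label == ion_type and comp.startswith(element.upper()[:1]):
            return comp
    return element.upper()


def _atom_line(record: str, serial: int, name: str, resname: str,
               chain: str, seq: int, coords: np.ndarray, occ: float,
               element: str) -> str:
    elem = element.upper()
    if len(elem) >= 2:
        name_field = f"{name[:4]:<4s}"
    else:
        name_field = _pdb_atom_name_field(name)
    return (
        f"{record:<6s}{serial % 100000:5d} {name_field} {resname:<3s} "
        f"{chain[:1]}{seq % 10000:4d}    "
        f"{coords[0]:8.3f}{coords[1]:8.3f}{coords[2]:8.3f}"
        f"{occ:6.2f}{0.0:6.2f}          {elem:>2s}"
    )
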