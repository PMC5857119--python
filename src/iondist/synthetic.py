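"""Synthetic structures with known ground truth.

The generator builds PDB-format fixtures from two ingredients: template
residues placed under arbitrary proper rigid motions, and ions planted
at chosen (r, theta, phi) positions in a chosen residue's local frame.
Because the planted local coordinates are known exactly, the fixtures
close the loop on the whole pipeline: parsing, frame construction and
coordinate mapping must recover what was planted, for any rigid motion
of the anchor residue.

Templates are schematic: backbone atoms (N, CA, C, O) use standard bond
lengths and angles, side-chain heavy atoms carry the correct names and
elements for each amino acid but are laid out as a zig-zag chain with
standard bond lengths rather than real rotamer or ring geometry.  The
local frame depends only on the geometry center and the N and C atoms,
so schematic side chains do not affect any frame-based quantity; they
merely give each residue the right atom inventory and a plausible bulk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from . import local_geometry as lg
from .structure_io import (
    CANONICAL_AA, ION_TABLE, Atom, IonSite, Residue, Structure,
    _ion_element, structure_to_pdb,
)

logger = logging.getLogger(__name__)

#: Side-chain heavy-atom names (PDB convention) per amino acid.
SIDECHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3",
            "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CB", "CG1", "CG2"),
}

_BOND_CC = 1.53
_BOND_CAN = 1.458
_BOND_CAC = 1.524
_BOND_CO = 1.231


def _element_of(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch
    raise ValueError(f"cannot infer element from {atom_name!r}")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _template_coords(aa_type: str) -> dict[str, np.ndarray]:
    """Template heavy-atom coordinates with CA at the origin."""
    ca = np.zeros(3)
    n = np.array([_BOND_CAN, 0.0, 0.0])
    ang = np.deg2rad(110.0)
    c = _BOND_CAC * np.array([np.cos(ang), np.sin(ang), 0.0])
    # carbonyl O: CA-C-O angle ~121 deg, in plane, anti to the N side
    v1 = _unit(ca - c)
    phi_o = np.deg2rad(-121.0)
    rot_z = np.array([[np.cos(phi_o), -np.sin(phi_o), 0.0],
                      [np.sin(phi_o), np.cos(phi_o), 0.0],
                      [0.0, 0.0, 1.0]])
    o = c + _BOND_CO * (rot_z @ v1)
    coords = {"N": n, "CA": ca, "C": c, "O": o}
    names = SIDECHAIN_ATOMS[aa_type]
    if names:
        # CB roughly tetrahedral to N and C, below the backbone plane
        cb_dir = _unit(np.array([-0.4, -0.6, -0.8]))
        cb = ca + _BOND_CC * cb_dir
        coords["CB"] = cb
        # remaining atoms: planar zig-zag away from the backbone
        e = _unit(np.array([-0.2, -0.9, -0.4]))
        f = _unit(np.cross(e, np.array([1.0, 0.0, 0.0])))
        delta = np.deg2rad(34.0)
        pos = cb
        for k, name in enumerate(names[1:]):
            sign = 1.0 if k % 2 == 0 else -1.0
            step = np.cos(delta) * e + sign * np.sin(delta) * f
            pos = pos + _BOND_CC * step
            coords[name] = pos
    return coords


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (det R = +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def random(cls, rng: np.random.Generator,
               translation_scale: float = 50.0) -> "RigidTransform":
        rot = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-translation_scale, translation_scale, size=3)
        return cls(rot, t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation


def make_residue(aa_type: str, transform: RigidTransform | None = None,
                 chain_id: str = "A", seq_id: int = 1) -> Residue:
    """Template residue mapped through a rigid transform."""
    if aa_type not in CANONICAL_AA:
        raise ValueError(f"unknown amino-acid type {aa_type!r}")
    transform = transform or RigidTransform.identity()
    coords = _template_coords(aa_type)
    atoms = [
        Atom(name=name, element=_element_of(name),
             coords=transform.apply(xyz))
        for name, xyz in coords.items()
    ]
    return Residue(aa_type=aa_type, chain_id=chain_id, seq_id=seq_id,
                   atoms=atoms)


def place_ion(frame: lg.LocalFrame, r: float, theta: float,
              phi: float) -> np.ndarray:
    """Global position whose local coordinates in ``frame`` are
    (r, theta, phi)."""
    if r < 0:
        raise ValueError("r must be non-negative")
    return lg.from_local(frame, lg.polar_to_cart(r, theta, phi))


# ---------------------------------------------------------------------------
# Fixture specification


@dataclass
class IonPlacement:
    """An ion planted either at (r, theta, phi) in an anchor residue's
    frame or at an absolute position."""

    ion_type: str
    anchor: int | None = None
    polar: tuple[float, float, float] | None = None
    position: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if (self.anchor is None) == (self.position is None):
            raise ValueError("specify exactly one of anchor+polar, position")
        if self.anchor is not None and self.polar is None:
            raise ValueError("anchored placement needs (r, theta, phi)")
        if self.polar is not None and self.polar[0] < 0:
            raise ValueError("r must be non-negative")


@dataclass
class FixtureSpec:
    """Declarative description of one synthetic structure."""

    residues: list[tuple[str, RigidTransform]] = field(default_factory=list)
    ions: list[IonPlacement] = field(default_factory=list)
    source_id: str = "synt"

    def to_json(self) -> str:
        return json.dumps({
            "source_id": self.source_id,
            "residues": [
                {"aa_type": aa, "rotation": t.rotation.tolist(),
                 "translation": t.translation.tolist()}
                for aa, t in self.residues
            ],
            "ions": [
                {"ion_type": p.ion_type, "anchor": p.anchor,
                 "polar": list(p.polar) if p.polar else None,
                 "position": list(p.position) if p.position else None}
                for p in self.ions
            ],
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FixtureSpec":
        doc = json.loads(text)
        return cls(
            source_id=doc.get("source_id", "synt"),
            residues=[
                (r["aa_type"],
                 RigidTransform(np.array(r["rotation"]),
                                np.array(r["translation"])))
                for r in doc["residues"]
            ],
            ions=[
                IonPlacement(
                    ion_type=p["ion_type"], anchor=p["anchor"],
                    polar=tuple(p["polar"]) if p["polar"] else None,
                    position=tuple(p["position"]) if p["position"] else None,
                )
                for p in doc["ions"]
            ],
        )


def make_structure(spec: FixtureSpec) -> Structure:
    """Instantiate a fixture spec as an in-memory :class:`Structure`."""
    residues = [
        make_residue(aa, t, chain_id="A", seq_id=i + 1)
        for i, (aa, t) in enumerate(spec.residues)
    ]
    frames = [lg.build_frame(r) for r in residues]
    ions = []
    for p in spec.ions:
        if p.anchor is not None:
            pos = place_ion(frames[p.anchor], *p.polar)
        else:
            pos = np.asarray(p.position, dtype=float)
        ions.append(IonSite(ion_type=p.ion_type,
                            element=_ion_element_symbol(p.ion_type),
                            coords=pos, source_id=spec.source_id,
                            chain_id="A"))
    st = Structure(source_id=spec.source_id, residues=residues, ions=ions)
    _warn_on_overlaps(st)
    return st


def make_pdb_fixture(spec: FixtureSpec) -> str:
    """Render a fixture spec as PDB-format text (deterministic)."""
    return structure_to_pdb(make_structure(spec))


def _ion_element_symbol(ion_type: str) -> str:
    sym = _ion_element(ion_type)
    if sym == "X":
        raise ValueError(f"unknown ion label {ion_type!r}")
    return sym


def _warn_on_overlaps(st: Structure, min_dist: float = 0.5) -> None:
    xyz = [a.coords for r in st.residues for a in r.atoms]
    xyz += [ion.coords for ion in st.ions]
    pts = np.array(xyz)
    if len(pts) < 2:
        return
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    iu = np.triu_indices(len(pts), k=1)
    n_close = int(np.sum(d[iu] < min_dist))
    if n_close:
        logger.warning("fixture contains %d atom pairs closer than %.1f A",
                       n_close, min_dist)


def random_fixture(rng: np.random.Generator, n_residues: int = 5,
                   n_ions: int = 3, spacing: float = 25.0,
                   r_range: tuple[float, float] = (2.5, 5.5),
                   cos_theta_max: float = 0.9,
                   octant_margin: float = 0.0) -> FixtureSpec:
    """Random fixture: residues on a loose grid, each ion anchored to a
    random residue at a random well-conditioned (r, theta, phi).

    ``octant_margin`` > 0 resamples angles until every local Cartesian
    component exceeds the margin, keeping planted points away from
    octant boundaries (useful when the octant itself is the ground
    truth being recovered through finite-precision PDB text).
    """
    residues = []
    for i in range(n_residues):
        t = RigidTransform.random(rng, translation_scale=1.0)
        grid = np.array([i % 3, (i // 3) % 3, i // 9], dtype=float)
        t = RigidTransform(t.rotation, t.translation + spacing * grid)
        residues.append((str(rng.choice(CANONICAL_AA)), t))
    ion_labels = sorted(set(ION_TABLE.values()))
    ions = []
    for _ in range(n_ions):
        anchor = int(rng.integers(n_residues))
        while True:
            r = float(rng.uniform(*r_range))
            theta = float(np.arccos(rng.uniform(-cos_theta_max,
                                                cos_theta_max)))
            phi = float(rng.uniform(-np.pi, np.pi))
            cart = lg.polar_to_cart(r, theta, phi)
            if np.min(np.abs(cart)) >= octant_margin:
                break
        ions.append(IonPlacement(ion_type=str(rng.choice(ion_labels)),
                                 anchor=anchor, polar=(r, theta, phi)))
    return FixtureSpec(residues=residues, ions=ions,
                       source_id=f"sy{rng.integers(100):02d}")
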