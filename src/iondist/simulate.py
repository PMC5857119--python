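"""Planted-model simulations for end-to-end validation.

A :class:`PlantedIonModel` defines a known generative process for
ion-amino-acid pairs: each candidate ion prefers one amino-acid type
and one octant of the residue-local frame.  Training structures sampled
from the model yield a statistics database whose planted preferences
are known exactly, and held-out sites sampled from the same process
give labelled prediction problems whose difficulty is controlled.

Ions are deliberately planted in *pairs that share a preferred amino
acid but differ in preferred octant*: the amino-acid-composition
predictor cannot separate the two partners (they tie near rank 1.5),
while the octant-resolved predictor can.  This makes the simulation a
direct probe of the value of angular resolution, not just of signal
strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import local_geometry as lg
from .ion_prediction import DEFAULT_CANDIDATES
from .structure_io import CANONICAL_AA, IonSite, Structure
from .synthetic import RigidTransform, make_residue, _ion_element_symbol


@dataclass
class PlantedIonModel:
    """Generative model with per-ion amino-acid and octant preferences.

    Ion number i prefers amino acid ``CANONICAL_AA[i // 2]`` (so
    consecutive ions share it) with probability ``aa_preference`` and
    octant ``(3 i) mod 8`` with probability ``octant_preference``; the
    remaining mass is uniform.  Radii are uniform on ``r_range`` and
    directions uniform within the sampled octant, kept
    ``octant_margin`` away from the octant boundary planes so the
    planted octant is unambiguous.
    """

    candidates: tuple[str, ...] = DEFAULT_CANDIDATES
    aa_preference: float = 0.7
    octant_preference: float = 0.8
    r_range: tuple[float, float] = (2.5, 5.5)
    octant_margin: float = 0.15
    preferred_aa: dict[str, str] = field(init=False)
    preferred_octant: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.preferred_aa = {
            ion: CANONICAL_AA[i // 2] for i, ion in enumerate(self.candidates)
        }
        self.preferred_octant = {
            ion: (3 * i) % 8 for i, ion in enumerate(self.candidates)
        }

    # -- elementary draws ----------------------------------------------------

    def sample_aa(self, ion: str, rng: np.random.Generator) -> str:
        if rng.random() < self.aa_preference:
            return self.preferred_aa[ion]
        others = [a for a in CANONICAL_AA if a != self.preferred_aa[ion]]
        return str(rng.choice(others))

    def sample_octant(self, ion: str, rng: np.random.Generator) -> int:
        if rng.random() < self.octant_preference:
            return self.preferred_octant[ion]
        others = [o for o in range(8) if o != self.preferred_octant[ion]]
        return int(rng.choice(others))

    def sample_local_cart(self, ion: str,
                          rng: np.random.Generator) -> np.ndarray:
        """Local Cartesian ion position in the planted octant."""
        octant = self.sample_octant(ion, rng)
        signs = np.array([
            -1.0 if octant & 4 else 1.0,
            -1.0 if octant & 2 else 1.0,
            -1.0 if octant & 1 else 1.0,
        ])
        while True:
            u = np.abs(rng.normal(size=3))
            u /= np.linalg.norm(u)
            if np.min(u) >= self.octant_margin:
                break
        r = rng.uniform(*self.r_range)
        return r * u * signs

    # -- structure-level sampling -------------------------------------------

    def sample_training_structures(
            self, n_per_class: int, rng: np.random.Generator,
            pairs_per_structure: int = 100) -> list[Structure]:
        """Isolated residue-ion pairs, ``n_per_class`` per candidate ion.

        Pairs are laid out on a 30-angstrom grid so no ion strays into
        another residue's pairing radius; each residue gets a random
        orientation, and the ion is planted at the sampled local
        position through the residue's own frame.
        """
        jobs = [ion for ion in self.candidates for _ in range(n_per_class)]
        structures: list[Structure] = []
        for start in range(0, len(jobs), pairs_per_structure):
            chunk = jobs[start:start + pairs_per_structure]
            residues, ions = [], []
            side = int(np.ceil(len(chunk) ** (1 / 3))) or 1
            for k, ion in enumerate(chunk):
                cell = 30.0 * np.array([k % side, (k // side) % side,
                                        k // (side * side)], dtype=float)
                t = RigidTransform(
                    RigidTransform.random(rng).rotation, cell)
                res = make_residue(self.sample_aa(ion, rng), t,
                                   seq_id=k + 1)
                frame = lg.build_frame(res)
                pos = lg.from_local(frame, self.sample_local_cart(ion, rng))
                residues.append(res)
                ions.append(IonSite(ion_type=ion,
                                    element=_ion_element_symbol(ion),
                                    coords=pos, chain_id="A",
                                    source_id=f"train{start}"))
            structures.append(Structure(source_id=f"train{start}",
                                        residues=residues, ions=ions))
        return structures

    def sample_site(self, ion: str, rng: np.random.Generator,
                    n_neighbors: int = 4
                    ) -> tuple[Structure, np.ndarray, str]:
        """One held-out site: neighbors arranged so the query position
        has the planted local coordinates in every neighbor's frame.

        The true ion is *not* placed in the structure (the site is
        masked); only its position and label are returned.
        """
        query = rng.uniform(-5.0, 5.0, size=3)
        residues = []
        for k in range(n_neighbors):
            aa = self.sample_aa(ion, rng)
            cart = self.sample_local_cart(ion, rng)
            rot = RigidTransform.random(rng).rotation
            template = make_residue(aa, seq_id=k + 1)
            frame0 = lg.build_frame(template)
            local_global = lg.from_local(frame0, cart)
            t = query - rot @ local_global
            residues.append(make_residue(aa, RigidTransform(rot, t),
                                         seq_id=k + 1))
        st = Structure(source_id=f"site-{ion}", residues=residues, ions=[])
        return st, query, ion

    def sample_sites(self, n_sites: int, rng: np.random.Generator,
                     n_neighbors: int = 4
                     ) -> list[tuple[Structure, np.ndarray, str]]:
        """Round-robin over candidate ions."""
        return [
            self.sample_site(self.candidates[i % len(self.candidates)],
                             rng, n_neighbors)
            for i in range(n_sites)
        ]
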