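"""Ion-amino-acid pair extraction and the aggregated statistics tables.

An *ion-amino-acid pair* is an ion whose distance to the geometry center
(GC) of a residue is within a cutoff (default 6 angstrom).  Each pair
carries the ion's coordinates in the residue's local frame.  Streaming
pairs from many structures fills a :class:`StatsDB`: occurrence counts
per amino acid, per ion, per (amino acid, ion) and per (amino acid, ion,
octant), radial and angular histograms, a per-amino-acid 3-D density
grid, and side-chain/backbone ion counts.  The StatsDB is the trained
artifact consumed by the ion-type predictor and by the amino-acid
clustering.

The side-chain preference R = N_s / (N_s + N_c) measures the fraction
of nearby ions sitting closer to the side-chain center than to the
backbone center; both counts use the shrunken radius
r_a = cutoff - max(r_c, r_s), where r_c and r_s are the distances from
the backbone and side-chain centers to the whole-residue GC.  R is
undefined for glycine, whose side chain has no heavy atom.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import local_geometry as lg
from .structure_io import CANONICAL_AA, Residue, Structure

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 6.0

#: Backbone heavy atoms; everything else in a residue is side chain.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: Side-chain property groups used for summary tables.  Glycine sits in
#: the uncharged-polar column by convention; the grouping argument of
#: :func:`group_summary` lets callers move it.
DEFAULT_GROUPS: dict[str, tuple[str, ...]] = {
    "non-polar": ("ALA", "ILE", "LEU", "MET", "PHE", "PRO", "TRP", "VAL"),
    "polar uncharged": ("ASN", "CYS", "GLN", "GLY", "SER", "THR", "TYR"),
    "positive": ("ARG", "HIS", "LYS"),
    "negative": ("ASP", "GLU"),
}


@dataclass
class BinConfig:
    """Histogram geometry: radial bin width, angular grid, density grid."""

    radial_width: float = 0.1
    theta_bins: int = 18
    phi_bins: int = 36
    density_bins: int = 12

    def radial_nbins(self, cutoff: float) -> int:
        return int(round(cutoff / self.radial_width))


@dataclass
class PairRecord:
    """One ion-amino-acid pair with the ion's local coordinates."""

    aa_type: str
    ion_type: str
    local: lg.LocalCoord
    gc_distance: float
    source_id: str = ""
    chain_id: str = ""


class SideChainUndefined(ValueError):
    """Side-chain preference is not defined (glycine)."""


@dataclass
class SideChainSplit:
    """Backbone/side-chain ion partition of one residue's pairs."""

    backbone_center: np.ndarray
    sidechain_center: np.ndarray
    r_c: float
    r_s: float
    r_a: float
    n_c: int
    n_s: int

    @property
    def R(self) -> float | None:
        total = self.n_c + self.n_s
        if total == 0:
            return None
        return self.n_s / total


def find_pairs(structure: Structure, cutoff: float = DEFAULT_CUTOFF
               ) -> list[PairRecord]:
    """All (residue, ion) pairs with GC distance <= cutoff.

    Ions pair with residues of any chain.  Residues whose frame cannot
    be built (missing or degenerate backbone) are skipped with a log
    entry.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not structure.residues or not structure.ions:
        return []
    frames: list[lg.LocalFrame | None] = []
    for res in structure.residues:
        try:
            frames.append(lg.build_frame(res))
        except (lg.FrameUndefined, lg.FrameDegenerate) as exc:
            logger.warning("%s: residue skipped: %s", structure.source_id, exc)
            frames.append(None)
    centers = np.array(
        [f.origin if f is not None else [np.nan] * 3 for f in frames]
    )
    ion_xyz = np.array([ion.coords for ion in structure.ions])
    dist = cdist(centers, ion_xyz)
    pairs: list[PairRecord] = []
    for i, res in enumerate(structure.residues):
        if frames[i] is None:
            continue
        for j, ion in enumerate(structure.ions):
            d = dist[i, j]
            if d <= cutoff:
                pairs.append(
                    PairRecord(
                        aa_type=res.aa_type,
                        ion_type=ion.ion_type,
                        local=lg.to_local(frames[i], ion.coords),
                        gc_distance=float(d),
                        source_id=ion.source_id or structure.source_id,
                        chain_id=res.chain_id,
                    )
                )
    return pairs


def side_chain_preference(pairs: Sequence[PairRecord], residue: Residue,
                          cutoff: float = DEFAULT_CUTOFF) -> SideChainSplit:
    """Partition a residue's paired ions between backbone and side chain.

    An ion within ``r_a`` of both centers contributes to both counts.
    Raises :class:`SideChainUndefined` for glycine.
    """
    if residue.aa_type == "GLY":
        raise SideChainUndefined("R is undefined for glycine")
    backbone = [a.coords for a in residue.atoms if a.name in BACKBONE_ATOMS]
    side = [a.coords for a in residue.atoms if a.name not in BACKBONE_ATOMS]
    if not backbone or not side:
        raise SideChainUndefined(
            f"{residue.aa_type}: missing backbone or side-chain atoms"
        )
    gc = lg.geometry_center(residue.atoms)
    bb_center = np.mean(backbone, axis=0)
    sc_center = np.mean(side, axis=0)
    r_c = float(np.linalg.norm(bb_center - gc))
    r_s = float(np.linalg.norm(sc_center - gc))
    r_a = cutoff - max(r_c, r_s)
    frame = lg.build_frame(residue)
    n_c = n_s = 0
    for p in pairs:
        ion_xyz = lg.from_local(frame, p.local.cart)
        if np.linalg.norm(ion_xyz - bb_center) <= r_a:
            n_c += 1
        if np.linalg.norm(ion_xyz - sc_center) <= r_a:
            n_s += 1
    return SideChainSplit(bb_center, sc_center, r_c, r_s, r_a, n_c, n_s)


# ---------------------------------------------------------------------------
# StatsDB


@dataclass
class StatsDB:
    """Aggregated ion-amino-acid statistics.

    Counts: ``n_aa`` counts every parsed residue (paired or not),
    ``n_ion`` every accepted ion, ``n_pair``/``n_pair_octant`` the pair
    tables.  Histograms are stored at the :class:`BinConfig` geometry.
    """

    cutoff: float = DEFAULT_CUTOFF
    bins: BinConfig = field(default_factory=BinConfig)
    n_structures: int = 0
    n_aa: dict[str, int] = field(default_factory=dict)
    n_ion: dict[str, int] = field(default_factory=dict)
    n_pair: dict[tuple[str, str], int] = field(default_factory=dict)
    n_pair_octant: dict[tuple[str, str, int], int] = field(default_factory=dict)
    radial_hist: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    angular_hist: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    density3d: dict[str, np.ndarray] = field(default_factory=dict)
    sidechain_counts: dict[str, list[int]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    # -- incremental building ------------------------------------------------

    def _empty_radial(self) -> np.ndarray:
        return np.zeros(self.bins.radial_nbins(self.cutoff), dtype=np.int64)

    def _empty_angular(self) -> np.ndarray:
        return np.zeros((self.bins.theta_bins, self.bins.phi_bins),
                        dtype=np.int64)

    def _empty_density(self) -> np.ndarray:
        nb = self.bins.density_bins
        return np.zeros((nb, nb, nb), dtype=np.int64)

    def add_pair(self, pair: PairRecord) -> None:
        key = (pair.aa_type, pair.ion_type)
        self.n_pair[key] = self.n_pair.get(key, 0) + 1
        okey = key + (pair.local.octant,)
        self.n_pair_octant[okey] = self.n_pair_octant.get(okey, 0) + 1

        r, theta, phi = pair.local.polar
        rad = self.radial_hist.setdefault(key, self._empty_radial())
        ri = min(int(r / self.bins.radial_width), rad.size - 1)
        rad[ri] += 1

        ang = self.angular_hist.setdefault(key, self._empty_angular())
        ti = min(int(theta / np.pi * self.bins.theta_bins),
                 self.bins.theta_bins - 1)
        pi_ = min(int((phi + np.pi) / (2 * np.pi) * self.bins.phi_bins),
                  self.bins.phi_bins - 1)
        ang[ti, pi_] += 1

        den = self.density3d.setdefault(pair.aa_type, self._empty_density())
        nb = self.bins.density_bins
        width = 2 * self.cutoff / nb
        idx = np.floor((pair.local.cart + self.cutoff) / width).astype(int)
        idx = np.clip(idx, 0, nb - 1)
        den[tuple(idx)] += 1

    def add_structure(self, structure: Structure,
                      pairs: Sequence[PairRecord] | None = None) -> None:
        if pairs is None:
            pairs = find_pairs(structure, self.cutoff)
        self.n_structures += 1
        for res in structure.residues:
            self.n_aa[res.aa_type] = self.n_aa.get(res.aa_type, 0) + 1
        for ion in structure.ions:
            self.n_ion[ion.ion_type] = self.n_ion.get(ion.ion_type, 0) + 1
        for p in pairs:
            self.add_pair(p)
        self._accumulate_sidechain(structure)

    def _accumulate_sidechain(self, structure: Structure) -> None:
        ion_xyz = np.array([ion.coords for ion in structure.ions])
        for res in structure.residues:
            if res.aa_type == "GLY" or not len(ion_xyz):
                continue
            try:
                frame = lg.build_frame(res)
            except (lg.FrameUndefined, lg.FrameDegenerate):
                continue
            d = np.linalg.norm(ion_xyz - frame.origin, axis=1)
            near = np.where(d <= self.cutoff)[0]
            if near.size == 0:
                continue
            res_pairs = [
                PairRecord(res.aa_type, structure.ions[j].ion_type,
                           lg.to_local(frame, structure.ions[j].coords),
                           float(d[j]), structure.source_id, res.chain_id)
                for j in near
            ]
            try:
                split = side_chain_preference(res_pairs, res, self.cutoff)
            except SideChainUndefined:
                continue
            cnt = self.sidechain_counts.setdefault(res.aa_type, [0, 0])
            cnt[0] += split.n_c
            cnt[1] += split.n_s

    # -- derived quantities --------------------------------------------------

    @property
    def total_pairs(self) -> int:
        return sum(self.n_pair.values())

    def pairs_for_aa(self, aa: str) -> int:
        return sum(v for (a, _), v in self.n_pair.items() if a == aa)

    def sidechain_R(self, aa: str) -> float | None:
        cnt = self.sidechain_counts.get(aa)
        if cnt is None or sum(cnt) == 0:
            return None
        return cnt[1] / (cnt[0] + cnt[1])

    def merge(self, other: "StatsDB") -> "StatsDB":
        """Additive merge; both databases must share cutoff and bins."""
        if self.cutoff != other.cutoff or self.bins != other.bins:
            raise ValueError("cannot merge StatsDBs with different geometry")
        out = StatsDB(cutoff=self.cutoff, bins=self.bins,
                      metadata=dict(self.metadata))
        out.n_structures = self.n_structures + other.n_structures
        for src in (self, other):
            for k, v in src.n_aa.items():
                out.n_aa[k] = out.n_aa.get(k, 0) + v
            for k, v in src.n_ion.items():
                out.n_ion[k] = out.n_ion.get(k, 0) + v
            for k, v in src.n_pair.items():
                out.n_pair[k] = out.n_pair.get(k, 0) + v
            for k, v in src.n_pair_octant.items():
                out.n_pair_octant[k] = out.n_pair_octant.get(k, 0) + v
            for k, v in src.radial_hist.items():
                out.radial_hist[k] = out.radial_hist.get(
                    k, out._empty_radial()) + v
            for k, v in src.angular_hist.items():
                out.angular_hist[k] = out.angular_hist.get(
                    k, out._empty_angular()) + v
            for k, v in src.density3d.items():
                out.density3d[k] = out.density3d.get(
                    k, out._empty_density()) + v
            for k, v in src.sidechain_counts.items():
                cnt = out.sidechain_counts.setdefault(k, [0, 0])
                cnt[0] += v[0]
                cnt[1] += v[1]
        return out

    # -- serialization -------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "cutoff": self.cutoff,
            "bins": asdict(self.bins),
            "n_structures": self.n_structures,
            "n_aa": self.n_aa,
            "n_ion": self.n_ion,
            "n_pair": [[a, i, v] for (a, i), v in sorted(self.n_pair.items())],
            "n_pair_octant": [
                [a, i, o, v]
                for (a, i, o), v in sorted(self.n_pair_octant.items())
            ],
            "radial_hist": [
                [a, i, v.tolist()]
                for (a, i), v in sorted(self.radial_hist.items())
            ],
            "angular_hist": [
                [a, i, v.tolist()]
                for (a, i), v in sorted(self.angular_hist.items())
            ],
            "density3d": [
                [a, v.tolist()] for a, v in sorted(self.density3d.items())
            ],
            "sidechain_counts": self.sidechain_counts,
            "metadata": self.metadata,
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StatsDB":
        doc = json.loads(text)
        db = cls(cutoff=doc["cutoff"], bins=BinConfig(**doc["bins"]),
                 n_structures=doc["n_structures"],
                 n_aa=dict(doc["n_aa"]), n_ion=dict(doc["n_ion"]),
                 metadata=doc.get("metadata", {}))
        db.n_pair = {(a, i): v for a, i, v in doc["n_pair"]}
        db.n_pair_octant = {
            (a, i, o): v for a, i, o, v in doc["n_pair_octant"]
        }
        db.radial_hist = {
            (a, i): np.array(v, dtype=np.int64)
            for a, i, v in doc["radial_hist"]
        }
        db.angular_hist = {
            (a, i): np.array(v, dtype=np.int64)
            for a, i, v in doc["angular_hist"]
        }
        db.density3d = {
            a: np.array(v, dtype=np.int64) for a, v in doc["density3d"]
        }
        db.sidechain_counts = {
            k: list(v) for k, v in doc["sidechain_counts"].items()
        }
        return db


def accumulate(structures: Iterable[Structure],
               cutoff: float = DEFAULT_CUTOFF,
               bins: BinConfig | None = None,
               metadata: Mapping | None = None) -> StatsDB:
    """Build a :class:`StatsDB` from a stream of structures."""
    db = StatsDB(cutoff=cutoff, bins=bins or BinConfig(),
                 metadata=dict(metadata or {}))
    for st in structures:
        db.add_structure(st)
    return db


# ---------------------------------------------------------------------------
# Summaries


def group_summary(source: "StatsDB | Mapping[str, float]",
                  grouping: Mapping[str, Sequence[str]] | None = None,
                  quantity: str = "pairs") -> pd.DataFrame:
    """Per-amino-acid values with per-group arithmetic means.

    ``source`` is either a StatsDB (quantity ``"pairs"`` for pair counts
    or ``"R"`` for the side-chain preference) or a ready mapping from
    amino acid to value.  Returns a tidy frame with columns ``group``,
    ``aa``, ``value``, ``group_mean``; amino acids with undefined values
    (glycine under ``"R"``) carry NaN and are excluded from the mean.
    """
    grouping = grouping or DEFAULT_GROUPS
    covered = [aa for aas in grouping.values() for aa in aas]
    if sorted(covered) != sorted(CANONICAL_AA):
        raise ValueError("grouping must cover the 20 amino acids exactly once")
    if isinstance(source, StatsDB):
        if quantity == "pairs":
            values = {aa: float(source.pairs_for_aa(aa))
                      for aa in CANONICAL_AA}
        elif quantity == "R":
            values = {
                aa: (np.nan if source.sidechain_R(aa) is None
                     else float(source.sidechain_R(aa)))
                for aa in CANONICAL_AA
            }
            values["GLY"] = np.nan
        else:
            raise ValueError(f"unknown quantity {quantity!r}")
    else:
        values = {aa: float(source.get(aa, np.nan)) for aa in CANONICAL_AA}
    rows = []
    for group, aas in grouping.items():
        vals = [values[aa] for aa in aas]
        mean = float(np.nanmean(vals)) if not all(np.isnan(vals)) else np.nan
        for aa in aas:
            rows.append(
                {"group": group, "aa": aa, "value": values[aa],
                 "group_mean": mean}
            )
    return pd.DataFrame(rows)


def histogram(db: StatsDB, aa: str, ion: str, kind: str) -> pd.DataFrame:
    """Stored histogram of one (amino acid, ion) combination.

    ``kind`` is ``radial`` (bin edges in angstrom), ``angular`` (theta x
    phi count grid) or ``octant`` (8 counts).  An absent combination
    yields an all-zero table.
    """
    key = (aa, ion)
    if kind == "radial":
        counts = db.radial_hist.get(key, db._empty_radial())
        edges = np.arange(counts.size + 1) * db.bins.radial_width
        return pd.DataFrame(
            {"r_lo": edges[:-1], "r_hi": edges[1:], "count": counts}
        )
    if kind == "angular":
        counts = db.angular_hist.get(key, db._empty_angular())
        return pd.DataFrame(
            counts,
            index=[f"theta{i}" for i in range(counts.shape[0])],
            columns=[f"phi{j}" for j in range(counts.shape[1])],
        )
    if kind == "octant":
        counts = [db.n_pair_octant.get(key + (o,), 0) for o in range(8)]
        return pd.DataFrame({"octant": range(8), "count": counts})
    raise ValueError(f"unknown histogram kind {kind!r}")


# ---------------------------------------------------------------------------
# Probability model (shared by prediction)


@dataclass
class ProbabilityModel:
    """Smoothed probability tables derived from a StatsDB.

    Add-alpha smoothing over the full (amino acid x ion) and (amino acid
    x ion x octant) grids keeps every probability strictly positive, so
    the product-form predictor is never annihilated by an unseen
    combination.  The marginals p(aa) and p(ion) are marginals of the
    smoothed joint over the pair table, making the pairwise ratio a
    pointwise-mutual-information-style quantity.
    """

    aa_labels: tuple[str, ...]
    ion_labels: tuple[str, ...]
    p_pair: np.ndarray       # (n_aa, n_ion)
    p_octant: np.ndarray     # (n_aa, n_ion, 8)
    p_aa: np.ndarray
    p_ion: np.ndarray
    alpha: float

    @classmethod
    def from_statsdb(cls, db: StatsDB, alpha: float = 1.0,
                     ions: Sequence[str] | None = None) -> "ProbabilityModel":
        aa_labels = CANONICAL_AA
        observed = sorted({i for (_, i) in db.n_pair})
        if ions is None:
            ion_labels = tuple(observed)
        else:
            ion_labels = tuple(sorted(set(ions) | set(observed)))
        if not ion_labels:
            raise ValueError("no ions observed and no candidate set given")
        na, ni = len(aa_labels), len(ion_labels)
        counts = np.zeros((na, ni))
        oct_counts = np.zeros((na, ni, 8))
        for (a, i), v in db.n_pair.items():
            counts[aa_labels.index(a), ion_labels.index(i)] = v
        for (a, i, o), v in db.n_pair_octant.items():
            oct_counts[aa_labels.index(a), ion_labels.index(i), o] = v
        joint = counts + alpha
        p_pair = joint / joint.sum()
        oct_joint = oct_counts + alpha
        p_octant = oct_joint / oct_joint.sum()
        return cls(
            aa_labels=tuple(aa_labels), ion_labels=ion_labels,
            p_pair=p_pair, p_octant=p_octant,
            p_aa=p_pair.sum(axis=1), p_ion=p_pair.sum(axis=0),
            alpha=alpha,
        )

    def aa_index(self, aa: str) -> int:
        return self.aa_labels.index(aa)

    def ion_index(self, ion: str) -> int:
        try:
            return self.ion_labels.index(ion)
        except ValueError:
            raise KeyError(
                f"unknown ion {ion!r}; candidates: {list(self.ion_labels)}"
            ) from None
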