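"""Clustering amino acids by the shape of their ion distributions.

Each amino acid's pooled ion density (a normalized 3-D histogram over
the local-frame ball) is treated as a feature.  Similarity between two
amino acids is the maximum Pearson correlation between one density and
rotated copies of the other, maximized over a discrete uniform grid of
rotations: amino acids whose ion clouds have the same shape in any
relative orientation come out similar.  The 20 x 20 similarity matrix
feeds complete-linkage hierarchical clustering; the dendrogram can be
exported as Newick text.

Rotating a voxel grid is done by nearest-neighbor pullback of bin
centers.  For the 24 rotations of the cube group the pullback is an
exact voxel permutation, so a map and its cube-rotated copy correlate
at exactly 1; for general grid rotations the correlation is exact up to
voxel resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.transform import Rotation

from .pair_statistics import StatsDB
from .structure_io import CANONICAL_AA

DEFAULT_GRID_STEP_DEG = 15.0


@dataclass
class DensityMap:
    """Normalized 3-D ion density around one amino acid.

    ``values`` is a cubic voxel grid over [-radius, radius]^3; only
    voxels whose centers lie inside the ball of the pairing radius carry
    mass, and the in-ball values sum to 1 unless the map is empty.
    """

    aa_type: str
    values: np.ndarray
    radius: float
    empty: bool = False

    @property
    def nbins(self) -> int:
        return self.values.shape[0]

    def bin_centers(self) -> np.ndarray:
        """(n^3, 3) voxel-center coordinates."""
        nb = self.nbins
        width = 2 * self.radius / nb
        axis = -self.radius + width * (np.arange(nb) + 0.5)
        gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    def support_mask(self) -> np.ndarray:
        """Flat boolean mask of voxels whose centers are inside the ball."""
        return np.linalg.norm(self.bin_centers(), axis=1) <= self.radius


def density_map(db: StatsDB, aa: str) -> DensityMap:
    """Pooled (all ion types) normalized density around one amino acid."""
    grid = db.density3d.get(aa)
    if grid is None or grid.sum() == 0:
        nb = db.bins.density_bins
        return DensityMap(aa_type=aa, values=np.zeros((nb, nb, nb)),
                          radius=db.cutoff, empty=True)
    values = grid.astype(float) / grid.sum()
    return DensityMap(aa_type=aa, values=values, radius=db.cutoff)


@lru_cache(maxsize=8)
def rotation_grid(step_deg: float = DEFAULT_GRID_STEP_DEG) -> tuple:
    """Deduplicated uniform grid over SO(3) from an Euler-angle lattice.

    The grid always contains the 24 proper rotations of the cube group
    (they arise from the 90-degree lattice points for any step dividing
    90).  Returned as a tuple of 3x3 matrices.
    """
    step = np.deg2rad(step_deg)
    alphas = np.arange(0, 2 * np.pi - 1e-9, step)
    betas = np.arange(0, np.pi + 1e-9, step)
    gammas = np.arange(0, 2 * np.pi - 1e-9, step)
    seen = {}
    for a in alphas:
        for b in betas:
            for g in gammas:
                rot = Rotation.from_euler("zyz", [a, b, g])
                q = rot.as_quat()
                if q[3] < 0 or (q[3] == 0 and q[0] < 0):
                    q = -q
                key = tuple(np.round(q, 6))
                if key not in seen:
                    seen[key] = rot.as_matrix()
    return tuple(seen.values())


_INDEX_MAP_CACHE: dict = {}


def _rotation_index_maps(map_shape: int, radius: float,
                         grid_step_deg: float
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Pullback index map per rotation (cached per bin geometry).

    For each rotation R and each in-ball voxel center c, find the voxel
    containing R^-1 c.  Returns (n_rot, n_support) source indices into
    the flat grid plus the support index array.
    """
    key = (map_shape, radius, grid_step_deg)
    if key in _INDEX_MAP_CACHE:
        return _INDEX_MAP_CACHE[key]
    rotations = rotation_grid(grid_step_deg)
    nb = map_shape
    width = 2 * radius / nb
    axis = -radius + width * (np.arange(nb) + 0.5)
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    centers = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    support = np.where(np.linalg.norm(centers, axis=1) <= radius)[0]
    sup_centers = centers[support]
    maps = np.empty((len(rotations), support.size), dtype=np.int64)
    for k, rot in enumerate(rotations):
        src = sup_centers @ rot  # == R^-1 applied to rows
        idx = np.floor((src + radius) / width).astype(np.int64)
        np.clip(idx, 0, nb - 1, out=idx)
        maps[k] = (idx[:, 0] * nb + idx[:, 1]) * nb + idx[:, 2]
    _INDEX_MAP_CACHE[key] = (maps, support)
    return maps, support


def rotation_correlation(a: DensityMap, b: DensityMap,
                         grid_step_deg: float = DEFAULT_GRID_STEP_DEG
                         ) -> float:
    """Maximum Pearson correlation between ``a`` and rotated copies of
    ``b`` over the rotation grid.

    A map with zero variance over the support (empty or constant) gives
    correlation 0 by convention.
    """
    if a.values.shape != b.values.shape or a.radius != b.radius:
        raise ValueError("density maps must share bin geometry")
    maps, support = _rotation_index_maps(a.nbins, a.radius, grid_step_deg)
    av = a.values.ravel()[support]
    a_c = av - av.mean()
    a_norm = np.linalg.norm(a_c)
    if a_norm == 0:
        return 0.0
    b_flat = b.values.ravel()
    rotated = b_flat[maps]                       # (n_rot, n_support)
    rotated_c = rotated - rotated.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(rotated_c, axis=1)
    ok = norms > 0
    if not ok.any():
        return 0.0
    corr = (rotated_c[ok] @ a_c) / (norms[ok] * a_norm)
    return float(corr.max())


def similarity_matrix(db: StatsDB,
                      grid_step_deg: float = DEFAULT_GRID_STEP_DEG,
                      aa_order: tuple[str, ...] = CANONICAL_AA) -> np.ndarray:
    """Rotation-maximized correlation between every pair of amino-acid
    densities (20 x 20, unit diagonal)."""
    dmaps = [density_map(db, aa) for aa in aa_order]
    n = len(dmaps)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = rotation_correlation(
                dmaps[i], dmaps[j], grid_step_deg)
    return sim


@dataclass
class Dendrogram:
    """Complete-linkage merge tree over labelled leaves."""

    labels: tuple[str, ...]
    merges: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges])


def cluster(similarity: np.ndarray,
            labels: tuple[str, ...] = CANONICAL_AA) -> Dendrogram:
    """Complete-linkage hierarchical clustering of 1 - similarity.

    The input must be symmetric with unit diagonal.  Cluster indices in
    the merge list follow the usual convention: leaves are 0..n-1, the
    k-th merge creates cluster n+k.
    """
    similarity = np.asarray(similarity, dtype=float)
    if similarity.ndim != 2 or similarity.shape[0] != similarity.shape[1]:
        raise ValueError("similarity must be square")
    if not np.allclose(similarity, similarity.T, atol=1e-10):
        raise ValueError("similarity matrix must be symmetric")
    n = similarity.shape[0]
    if len(labels) != n:
        raise ValueError("label count must match matrix size")
    dist = 1.0 - similarity
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices(n, k=1)]
    linkage = hierarchy.linkage(condensed, method="complete")
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in linkage]
    return Dendrogram(labels=tuple(labels), merges=merges)


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick text with leaf labels and branch lengths from merge
    heights (a leaf's branch length is its parent's merge height / 2 in
    ultrametric form)."""
    n = len(dendrogram.labels)
    height = {i: 0.0 for i in range(n)}
    node_str = {i: dendrogram.labels[i] for i in range(n)}
    for k, (a, b, h) in enumerate(dendrogram.merges):
        new = n + k
        la = h / 2 - height[a] / 2
        lb = h / 2 - height[b] / 2
        node_str[new] = (
            f"({node_str[a]}:{la:.6f},{node_str[b]}:{lb:.6f})"
        )
        height[new] = h
    root = n + len(dendrogram.merges) - 1 if dendrogram.merges else 0
    return node_str[root] + ";"
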