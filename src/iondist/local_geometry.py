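"""Per-residue local coordinate frames and coordinate transforms.

Every amino acid gets a right-handed orthonormal frame anchored on its
own geometry: the origin is the unweighted mean of the heavy atoms
(geometry center, GC), the x axis points from the GC to the backbone
nitrogen, the y axis is the direction to the carboxyl carbon after
Gram-Schmidt removal of its x component, and z completes the triad by
cross product.  Because the frame is built from the residue's own atoms,
coordinates of a nearby ion expressed in it are invariant under any
rigid motion of the complex — the property that lets ion positions from
unrelated structures be pooled into one distribution per amino acid.

Positions in the frame are also expressed in spherical polar form
(r, theta, phi) and reduced to one of eight octants given by the sign
pattern of (x, y, z); the octant is the angular resolution used by the
octant-resolved ion-type predictor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import Atom, Residue

#: Minimum norm (angstrom) accepted for the un-normalized axis vectors.
DEGENERACY_TOL = 1e-6


class FrameUndefined(ValueError):
    """The residue lacks the backbone atoms needed to build a frame."""


class FrameDegenerate(ValueError):
    """Backbone geometry is collinear/degenerate; no stable frame exists."""


@dataclass
class LocalFrame:
    """Origin plus right-handed orthonormal axes of one residue."""

    origin: np.ndarray
    x_hat: np.ndarray
    y_hat: np.ndarray
    z_hat: np.ndarray

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix whose rows are the axes: maps global offsets to
        local coordinates."""
        return np.vstack([self.x_hat, self.y_hat, self.z_hat])


@dataclass
class LocalCoord:
    """One point in a residue frame: Cartesian, polar and octant form."""

    cart: np.ndarray
    polar: tuple[float, float, float]
    octant: int
    at_origin: bool = False

    @property
    def r(self) -> float:
        return self.polar[0]


def geometry_center(atoms: list[Atom] | np.ndarray) -> np.ndarray:
    """Unweighted mean position of a residue's heavy atoms."""
    if isinstance(atoms, np.ndarray):
        coords = atoms
    else:
        coords = np.array([a.coords for a in atoms], dtype=float)
    if coords.size == 0:
        raise ValueError("geometry center of an empty atom list is undefined")
    return coords.mean(axis=0)


def build_frame(residue: Residue) -> LocalFrame:
    """Build the residue-local frame.

    Raises
    ------
    FrameUndefined
        if the backbone nitrogen "N" or carboxyl carbon "C" is missing.
    FrameDegenerate
        if either atom coincides with the geometry center or the N and C
        directions are parallel (norm of the orthogonalized y below
        :data:`DEGENERACY_TOL`).
    """
    n_atom = residue.get_atom("N")
    c_atom = residue.get_atom("C")
    if n_atom is None or c_atom is None:
        raise FrameUndefined(
            f"{residue.aa_type} {residue.chain_id}{residue.seq_id}: "
            "backbone N or C missing"
        )
    origin = geometry_center(residue.atoms)
    x = n_atom.coords - origin
    nx = np.linalg.norm(x)
    if nx < DEGENERACY_TOL:
        raise FrameDegenerate("backbone N coincides with the geometry center")
    x_hat = x / nx
    y_prime = c_atom.coords - origin
    y = y_prime - np.dot(x_hat, y_prime) * x_hat
    ny = np.linalg.norm(y)
    if ny < DEGENERACY_TOL:
        raise FrameDegenerate(
            "carboxyl-carbon direction is parallel to the N direction"
        )
    y_hat = y / ny
    z_hat = np.cross(x_hat, y_hat)
    return LocalFrame(origin=origin, x_hat=x_hat, y_hat=y_hat, z_hat=z_hat)


def octant_index(cart: np.ndarray) -> int:
    """Octant of a local-frame point: 4*[x<0] + 2*[y<0] + [z<0].

    Coordinates equal to zero count as non-negative, so boundaries are
    assigned deterministically.
    """
    x, y, z = cart
    return 4 * int(x < 0) + 2 * int(y < 0) + int(z < 0)


def cart_to_polar(cart: np.ndarray) -> tuple[float, float, float]:
    """Spherical polar (r, theta, phi); phi by the two-argument
    arctangent so quadrants are preserved.  r = 0 maps to (0, 0, 0)."""
    x, y, z = cart
    r = float(np.sqrt(x * x + y * y + z * z))
    if r == 0.0:
        return 0.0, 0.0, 0.0
    theta = float(np.arccos(np.clip(z / r, -1.0, 1.0)))
    phi = float(np.arctan2(y, x))
    return r, theta, phi


def polar_to_cart(r: float, theta: float, phi: float) -> np.ndarray:
    st = np.sin(theta)
    return np.array(
        [r * st * np.cos(phi), r * st * np.sin(phi), r * np.cos(theta)]
    )


def to_local(frame: LocalFrame, point: np.ndarray) -> LocalCoord:
    """Express a global-coordinate point in the residue frame."""
    p = np.asarray(point, dtype=float) - frame.origin
    cart = frame.rotation @ p
    polar = cart_to_polar(cart)
    return LocalCoord(
        cart=cart,
        polar=polar,
        octant=octant_index(cart),
        at_origin=polar[0] == 0.0,
    )


def from_local(frame: LocalFrame, cart: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_local` for Cartesian local coordinates."""
    return frame.origin + frame.rotation.T @ np.asarray(cart, dtype=float)
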