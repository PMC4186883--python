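"""Internal-coordinate geometry for reduced torsional models.

Molecules are described by a Z-matrix-like topology (:class:`AtomSpec`): each
atom after the first three is placed from three previously placed reference
atoms by a fixed bond length, a fixed bond angle and a dihedral that is either
frozen or indexed into the molecule's vector of rotatable dihedrals.  Only the
rotatable dihedrals move; bond lengths and angles are rigid.  All dihedrals are
reported on [0, 360) degrees so that the sterically closed state of a
C-C-S-S dihedral is the single interval 180 +/- 50 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtomSpec",
    "Conformation",
    "CartesianStructure",
    "DegenerateGeometryError",
    "wrap_angle",
    "to_signed",
    "dihedral",
    "build_cartesian",
    "distance",
]

#: sin(bond angle) below this is treated as a collinear (degenerate) frame
COLLINEAR_TOL = 1e-8


class DegenerateGeometryError(ValueError):
    """Raised when three points defining a dihedral frame are collinear."""


@dataclass(frozen=True)
class AtomSpec:
    """Placement rule for one atom of a torsional model.

    Parameters
    ----------
    name : str
        Atom label, e.g. ``"SG"``.
    element : str
        Element symbol.
    internal_refs : tuple of int
        Indices ``(a, b, c)`` of three already-placed atoms; the new atom
        bonds to ``c`` with angle at ``c`` against ``b`` and dihedral
        ``a-b-c-new``.  Ignored for the first three atoms (seeding
        convention: atom 0 at the origin, atom 1 on +x, atom 2 in the
        xy-plane with positive y).
    bond_length : float
        Bond length to the third reference atom, in Angstrom.
    bond_angle : float
        Bond angle in degrees, in (0, 180).
    dihedral_ref : int or float
        If an ``int``: index into the model's rotatable-dihedral vector.
        If a ``float``: fixed dihedral value in degrees.
    """

    name: str
    element: str
    internal_refs: tuple[int, int, int] = (-1, -1, -1)
    bond_length: float = 0.0
    bond_angle: float = 0.0
    dihedral_ref: int | float = 0.0

    def __post_init__(self) -> None:
        if self.internal_refs != (-1, -1, -1):
            if self.bond_length <= 0:
                raise ValueError(f"atom {self.name}: bond_length must be > 0")
            if not 0.0 < self.bond_angle < 180.0:
                raise ValueError(f"atom {self.name}: bond_angle must lie in (0, 180)")


@dataclass
class Conformation:
    """A vector of rotatable dihedrals, one per model torsion, in degrees."""

    dihedrals: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.dihedrals, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("conformation contains non-finite dihedrals")
        self.dihedrals = wrap_angle(arr)


@dataclass
class CartesianStructure:
    """Cartesian realization of a torsional model (coordinates in Angstrom)."""

    coords: np.ndarray
    names: list[str] = field(default_factory=list)
    elements: list[str] = field(default_factory=list)


def wrap_angle(angle):
    """Wrap an angle (degrees) into [0, 360).

    Accepts scalars or arrays; raises on non-finite input.
    """
    arr = np.asarray(angle, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("cannot wrap non-finite angle")
    wrapped = np.mod(arr, 360.0)
    # mod can return 360.0 for inputs just below a multiple of 360
    wrapped = np.where(wrapped >= 360.0, wrapped - 360.0, wrapped)
    if np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


def to_signed(angle):
    """Convert an angle (degrees) to the (-180, 180] convention."""
    w = wrap_angle(angle)
    arr = np.asarray(w, dtype=float)
    signed = np.where(arr > 180.0, arr - 360.0, arr)
    if np.ndim(angle) == 0:
        return float(signed)
    return signed


def dihedral(p1, p2, p3, p4) -> float:
    """Dihedral angle p1-p2-p3-p4 in degrees on [0, 360).

    IUPAC sign convention: cis/eclipsed = 0, positive sense is a clockwise
    rotation of p4 relative to p1 when sighting from p2 towards p3; the raw
    signed value is then wrapped to [0, 360).  The angle is invariant under
    reversal of the four points.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 == 0.0 or np.linalg.norm(n1) < COLLINEAR_TOL * max(1.0, np.linalg.norm(b1) * nb2):
        raise DegenerateGeometryError(
            f"collinear or coincident triple (p1, p2, p3) = {p1}, {p2}, {p3}"
        )
    if np.linalg.norm(n2) < COLLINEAR_TOL * max(1.0, nb2 * np.linalg.norm(b3)):
        raise DegenerateGeometryError(
            f"collinear or coincident triple (p2, p3, p4) = {p2}, {p3}, {p4}"
        )
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / nb2))
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def _place_atom(a, b, c, bond_length, bond_angle_rad, dihedral_rad):
    """NeRF placement of a new atom from reference positions a, b, c."""
    bc = c - b
    nbc = np.linalg.norm(bc)
    bc = bc / nbc
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < COLLINEAR_TOL * max(1.0, np.linalg.norm(ab)):
        raise DegenerateGeometryError(
            "ill-conditioned internal reference frame (collinear a, b, c)"
        )
    n = n / nn
    m = np.cross(n, bc)
    st = np.sin(bond_angle_rad)
    d_local = np.array(
        [
            -bond_length * np.cos(bond_angle_rad),
            bond_length * st * np.cos(dihedral_rad),
            bond_length * st * np.sin(dihedral_rad),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_cartesian(model, conf: Conformation) -> CartesianStructure:
    """Realize a torsional model at a given conformation in Cartesian space.

    Seeding convention: atom 0 at the origin, atom 1 along +x, atom 2 in the
    xy-plane with positive y.  Subsequent atoms are placed by NeRF from their
    ``internal_refs``.  Recomputing any rotatable dihedral from the output
    coordinates recovers the input value.
    """
    atoms = model.atoms
    n_tor = model.n_torsions
    phi = np.asarray(conf.dihedrals, dtype=float)
    if phi.shape != (n_tor,):
        raise ValueError(
            f"conformation has {phi.shape[0] if phi.ndim == 1 else phi.shape} dihedrals, "
            f"model {model.name!r} expects {n_tor}"
        )
    phi_rad = np.radians(phi)
    coords = np.zeros((len(atoms), 3))
    if len(atoms) < 3:
        raise ValueError("model must have at least 3 atoms")
    coords[1] = (atoms[1].bond_length, 0.0, 0.0)
    th2 = np.radians(atoms[2].bond_angle)
    if np.sin(th2) < COLLINEAR_TOL:
        raise DegenerateGeometryError("seed angle at atom 2 is collinear")
    # atom 2 bonds to atom 1; angle measured against atom 0; positive y
    coords[2] = coords[1] + atoms[2].bond_length * np.array(
        [-np.cos(th2), np.sin(th2), 0.0]
    )
    for i in range(3, len(atoms)):
        spec = atoms[i]
        a, b, c = (coords[j] for j in spec.internal_refs)
        if isinstance(spec.dihedral_ref, (int, np.integer)):
            tor = phi_rad[spec.dihedral_ref]
        else:
            tor = np.radians(spec.dihedral_ref)
        if np.sin(np.radians(spec.bond_angle)) < COLLINEAR_TOL:
            raise DegenerateGeometryError(f"collinear bond angle at atom {spec.name}")
        coords[i] = _place_atom(a, b, c, spec.bond_length, np.radians(spec.bond_angle), tor)
    return CartesianStructure(
        coords=coords,
        names=[a.name for a in atoms],
        elements=[a.element for a in atoms],
    )


def distance(structure: CartesianStructure, i: int, j: int) -> float:
    """Euclidean distance (Angstrom) between atoms i and j of a structure."""
    coords = structure.coords
    n = coords.shape[0]
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"atom index out of range: ({i}, {j}) for {n} atoms")
    return float(np.linalg.norm(coords[i] - coords[j]))
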