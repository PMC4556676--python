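"""Coordinate-level model: proteins, the implicit membrane slab, rigid-body math.

The membrane is a flat slab of hydrophobic thickness ``T`` (default 30 Å)
described by a center point, a unit normal and a sigmoid steepness.  The
signed depth of a point is its projection onto the normal, measured from the
center; the hydration fraction ``f(z)`` interpolates smoothly between the
membrane core (``f = 0``) and bulk water (``f = 1``), crossing ``1/2`` exactly
at the slab boundary ``|z| = T/2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "MembraneGeometry",
    "RigidTransform",
    "signed_depth",
    "hydration_fraction",
    "apply_transform",
    "superpose",
    "dihedral",
    "rotation_about_axis",
    "DegenerateGeometryError",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")


class DegenerateGeometryError(ValueError):
    """Raised for geometric inputs with no well-defined answer."""


@dataclass
class Atom:
    """A heavy atom with a transfer-energy category label.

    ``category`` ties the atom to a row of the active atom-transfer table
    (e.g. ``aliphatic_C``, ``charged_N``, ``backbone``).
    """

    name: str
    element: str
    pos: np.ndarray
    category: str = "backbone"

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")


@dataclass
class Residue:
    seq_id: int
    chain: str
    aa: str
    atoms: list[Atom] = field(default_factory=list)
    phi: float | None = None
    psi: float | None = None

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.chain}{self.seq_id} ({self.aa}) has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def ca(self) -> np.ndarray:
        return self.atom("CA").pos


@dataclass
class Structure:
    """Ordered chains of residues; the biomolecule half of a membrane pose."""

    chains: list[tuple[str, list[Residue]]]

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate chain ids: {ids}")
        if self.n_residues == 0:
            raise ValueError("structure must contain at least one residue")
        for cid, residues in self.chains:
            seq = [r.seq_id for r in residues]
            if any(b <= a for a, b in zip(seq, seq[1:])):
                raise ValueError(f"chain {cid}: residue numbers not strictly increasing")

    @property
    def n_residues(self) -> int:
        return sum(len(res) for _, res in self.chains)

    def residues(self) -> Iterator[Residue]:
        for _, res in self.chains:
            yield from res

    def chain(self, chain_id: str) -> list[Residue]:
        for cid, res in self.chains:
            if cid == chain_id:
                return res
        raise KeyError(f"no chain {chain_id!r}")

    def residue(self, chain_id: str, seq_id: int) -> Residue:
        for r in self.chain(chain_id):
            if r.seq_id == seq_id:
                return r
        raise KeyError(f"no residue {chain_id}{seq_id}")

    def coords(self) -> np.ndarray:
        """All atom positions as an (N, 3) array, in iteration order."""
        return np.array([a.pos for r in self.residues() for a in r.atoms], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        i = 0
        for r in self.residues():
            for a in r.atoms:
                a.pos = coords[i].copy()
                i += 1
        if i != len(coords):
            raise ValueError(f"coordinate count mismatch: {len(coords)} given, {i} needed")

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues()], dtype=float)

    def copy(self) -> "Structure":
        return Structure(
            [
                (
                    cid,
                    [
                        Residue(
                            r.seq_id,
                            r.chain,
                            r.aa,
                            [Atom(a.name, a.element, a.pos.copy(), a.category) for a in r.atoms],
                            r.phi,
                            r.psi,
                        )
                        for r in res
                    ],
                )
                for cid, res in self.chains
            ]
        )


@dataclass(frozen=True)
class MembraneGeometry:
    """The implicit slab: center, unit normal, hydrophobic thickness, steepness."""

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    thickness: float = 30.0
    steepness: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "normal", np.asarray(self.normal, dtype=float))
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-9:
            raise ValueError("membrane normal must be unit length")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")
        if self.steepness < 1:
            raise ValueError("steepness must be >= 1")

    @property
    def half_thickness(self) -> float:
        return 0.5 * self.thickness


def signed_depth(geom: MembraneGeometry, point: np.ndarray) -> float:
    """Signed distance of ``point`` from the membrane center plane (Å).

    ``|z| <= thickness/2`` iff the point lies inside the hydrophobic layer.
    """
    return float(np.dot(np.asarray(point, dtype=float) - geom.center, geom.normal))


def hydration_fraction(geom: MembraneGeometry, z: float | np.ndarray):
    """Water-like character of the environment at signed depth ``z``.

    ``f = u**n / (1 + u**n)`` with ``u = |2 z / T|``: zero at the slab center,
    exactly 1/2 at the hydrophobic boundary, approaching 1 in bulk water.
    Even in ``z`` and non-decreasing in ``|z|``.
    """
    u = np.abs(2.0 * np.asarray(z, dtype=float) / geom.thickness)
    n = geom.steepness
    # u**n overflows for points far outside the slab; compute in a stable form.
    with np.errstate(over="ignore"):
        un = u**n
        f = np.where(np.isinf(un), 1.0, un / (1.0 + un))
    return float(f) if np.isscalar(z) or np.ndim(z) == 0 else f


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with det +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def apply_transform(obj, t: RigidTransform):
    """Apply a rigid motion to a Structure (all atoms) or a MembraneGeometry.

    Membrane centers translate and rotate; the normal only rotates.
    """
    if isinstance(obj, Structure):
        out = obj.copy()
        out.set_coords(t.apply(out.coords()))
        return out
    if isinstance(obj, MembraneGeometry):
        return replace(obj, center=t.apply(obj.center), normal=obj.normal @ t.rotation.T)
    raise TypeError(f"cannot transform object of type {type(obj).__name__}")


def superpose(
    moving: Sequence[np.ndarray] | np.ndarray, fixed: Sequence[np.ndarray] | np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition (Kabsch) of ``moving`` onto ``fixed``.

    Returns the transform and the post-fit RMSD in Å.
    """
    P = np.asarray(moving, dtype=float)
    Q = np.asarray(fixed, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3 or len(P) < 3:
        raise ValueError("superpose needs two equally sized (n>=3, 3) point sets")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise DegenerateGeometryError("moving point set is (near-)collinear")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    transform = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(P) - Q) ** 2, axis=1))))
    return transform, rmsd


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix about a (not necessarily unit) axis through the origin."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise DegenerateGeometryError("rotation axis must be nonzero")
    k = axis / n
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))
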