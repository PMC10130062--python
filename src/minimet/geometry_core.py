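"""Rigid-body superposition and internal-coordinate geometry.

Shared by every structural analysis in the package: Kabsch
least-squares superposition (proper rotations only), distances, bond
angles, signed dihedrals in the IUPAC convention, and the chi1 rotamer
classification used for metal-binding cysteines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import Residue, Structure, StructureError

__all__ = [
    "Transform",
    "SuperposeResult",
    "GeometryError",
    "superpose",
    "superpose_structures",
    "distance",
    "angle",
    "dihedral",
    "chi1",
    "chi1_class",
    "BACKBONE_ATOMS",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

_GAMMA_ATOMS = ("SG", "OG", "OG1", "CG", "CG1", "SD")


class GeometryError(ValueError):
    """Raised for degenerate geometric input."""


@dataclass
class Transform:
    """Proper rigid-body motion x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float)
        self.translation = np.asarray(self.translation, float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise GeometryError("Transform needs a 3x3 rotation and a 3-vector translation")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise GeometryError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-9):
            raise GeometryError("rotation determinant is not +1 (improper rotation)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def compose(self, other: "Transform") -> "Transform":
        """self after other: x -> self(other(x))."""
        return Transform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "Transform":
        return Transform(self.rotation.T, -self.rotation.T @ self.translation)

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def about_axis(cls, point: np.ndarray, direction: np.ndarray, angle_deg: float) -> "Transform":
        """Rotation by ``angle_deg`` about the line through ``point`` along
        ``direction``."""
        from scipy.spatial.transform import Rotation

        point = np.asarray(point, float)
        u = np.asarray(direction, float)
        u = u / np.linalg.norm(u)
        R = Rotation.from_rotvec(np.radians(angle_deg) * u).as_matrix()
        return cls(R, point - R @ point)


@dataclass
class SuperposeResult:
    transform: Transform
    rmsd: float
    n_atoms: int
    atom_selection: str = ""


def superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperposeResult:
    """Least-squares optimal rigid superposition of ``mobile`` onto
    ``reference`` (Kabsch; proper rotation enforced).

    Returns the transform that moves the mobile set onto the reference
    and the post-fit RMSD.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise GeometryError(f"point sets must both be (n, 3); got {P.shape} vs {Q.shape}")
    n = len(P)
    if n < 3:
        raise GeometryError("superposition needs at least 3 points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    # collinear sets leave the rotation about the line undetermined
    if S[1] <= 1e-10 * max(S[0], 1.0):
        raise GeometryError("degenerate (collinear) point set: rotation is not unique")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(((moved - Q) ** 2).sum() / n))
    return SuperposeResult(Transform(R, t), rmsd, n)


def superpose_structures(
    mobile: Structure,
    reference: Structure,
    atoms: tuple[str, ...] = BACKBONE_ATOMS,
    residue_range: tuple[int, int] | None = None,
) -> SuperposeResult:
    """Superpose two structures on identically numbered residues.

    Residue correspondence is by (chain order, author seq_id); only
    residues present in both structures and carrying all requested atoms
    contribute.  The default atom set N/CA/C/O is the common reading of
    "backbone RMSD".
    """
    def collect(st: Structure) -> dict[tuple[int, int, str], np.ndarray]:
        out = {}
        for ci, chain in enumerate(st.chains.values()):
            for res in chain:
                if residue_range and not (residue_range[0] <= res.seq_id <= residue_range[1]):
                    continue
                if not res.has_atoms(*atoms):
                    continue
                for a in atoms:
                    out[(ci, res.seq_id, a)] = res.atom(a).coords
        return out

    ma, ra = collect(mobile), collect(reference)
    keys = sorted(set(ma) & set(ra))
    if len(keys) < 3:
        raise GeometryError("fewer than 3 matched atoms between the structures")
    result = superpose(np.array([ma[k] for k in keys]), np.array([ra[k] for k in keys]))
    result.atom_selection = ",".join(atoms)
    return result


# ---------------------------------------------------------------------------
# internal coordinates


def distance(p1, p2) -> float:
    """Euclidean distance in Angstrom."""
    return float(np.linalg.norm(np.asarray(p1, float) - np.asarray(p2, float)))


def angle(p1, p2, p3) -> float:
    """Bond angle p1-p2-p3 in degrees."""
    p1, p2, p3 = (np.asarray(p, float) for p in (p1, p2, p3))
    v1, v2 = p1 - p2, p3 - p2
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-10 or n2 < 1e-10:
        raise GeometryError("coincident points in angle computation")
    c = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, in (-180, 180].

    IUPAC sign convention: looking from p2 towards p3, a clockwise
    rotation of p4 relative to p1 is positive.
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError("undefined dihedral: three consecutive points are collinear")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = n1 @ n2
    y = m1 @ n2
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if np.isclose(ang, -180.0) else ang


def chi1(residue: Residue) -> float:
    """Side-chain chi1 torsion N-CA-CB-gamma in degrees.

    The gamma heavy atom is SG for Cys, OG/OG1 for Ser/Thr, CG/CG1/SD
    otherwise (first one present wins).
    """
    missing = [n for n in ("N", "CA", "CB") if not residue.has_atoms(n)]
    gamma = next((g for g in _GAMMA_ATOMS if residue.has_atoms(g)), None)
    if gamma is None:
        missing.append("gamma heavy atom (" + "/".join(_GAMMA_ATOMS) + ")")
    if missing:
        raise StructureError(
            f"residue {residue.name}{residue.seq_id}: missing atoms for chi1: {', '.join(missing)}"
        )
    return dihedral(
        residue.atom("N").coords,
        residue.atom("CA").coords,
        residue.atom("CB").coords,
        residue.atom(gamma).coords,
    )


def chi1_class(chi1_deg: float) -> str:
    """Rotamer class of a chi1 angle: ``g+`` (~+60), ``t`` (~180), ``g-`` (~-60).

    Boundaries at 0 and +/-120 degrees; g+ maps to chi1 around +60.
    """
    x = (chi1_deg + 180.0) % 360.0 - 180.0
    if 0.0 <= x < 120.0:
        return "g+"
    if -120.0 <= x < 0.0:
        return "g-"
    return "t"
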