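"""Rigid-body transforms and least-squares superposition.

Two independent optimal-superposition solvers are provided: the SVD-based
Kabsch algorithm (production path) and Horn's quaternion method (used as an
algorithmically independent cross-check in the test suite). Both minimise
the root-mean-square deviation over a correspondence-ordered pair of point
sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UnderdeterminedSuperposition


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def is_proper(self, tol: float = 1e-9) -> bool:
        r = self.rotation
        return (np.allclose(r @ r.T, np.eye(3), atol=tol)
                and abs(np.linalg.det(r) - 1.0) <= tol)

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.tolist(), "translation": self.translation.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.array(d["rotation"]), np.array(d["translation"]))


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain RMSD between two correspondence-ordered coordinate arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _check_superposable(reference: np.ndarray, mobile: np.ndarray) -> None:
    if reference.shape != mobile.shape or reference.ndim != 2 or reference.shape[1] != 3:
        raise UnderdeterminedSuperposition(
            f"point sets must be equal-shape (n, 3); got {reference.shape} vs {mobile.shape}")
    n = reference.shape[0]
    if n < 3:
        raise UnderdeterminedSuperposition(f"need >= 3 correspondence points, got {n}")
    # collinear sets leave a rotation about the line undetermined
    for pts in (reference, mobile):
        sv = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
        if sv[1] <= 1e-9 * max(sv[0], 1.0):
            raise UnderdeterminedSuperposition("degenerate (collinear) point set")


def kabsch(reference: np.ndarray, mobile: np.ndarray) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference`` (Kabsch, SVD).

    Returns the transform and the RMSD over the input correspondence after
    applying it.
    """
    reference = np.asarray(reference, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    _check_superposable(reference, mobile)
    ref_c = reference.mean(axis=0)
    mob_c = mobile.mean(axis=0)
    h = (mobile - mob_c).T @ (reference - ref_c)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = ref_c - rot @ mob_c
    transform = RigidTransform(rot, t)
    return transform, rmsd(reference, transform.apply(mobile))


def quaternion_superpose(reference: np.ndarray, mobile: np.ndarray) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition via Horn's closed-form quaternion method.

    Independent of :func:`kabsch` (eigendecomposition of the 4x4 key matrix
    instead of an SVD of the 3x3 cross-covariance); used to cross-validate it.
    """
    reference = np.asarray(reference, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    _check_superposable(reference, mobile)
    ref_c = reference.mean(axis=0)
    mob_c = mobile.mean(axis=0)
    m = (mobile - mob_c).T @ (reference - ref_c)
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    w, v = np.linalg.eigh(key)
    q = v[:, np.argmax(w)]  # unit quaternion (w, x, y, z)
    qw, qx, qy, qz = q
    rot = np.array([
        [1 - 2 * (qy * qy + qz * qz), 2 * (qx * qy - qz * qw), 2 * (qx * qz + qy * qw)],
        [2 * (qx * qy + qz * qw), 1 - 2 * (qx * qx + qz * qz), 2 * (qy * qz - qx * qw)],
        [2 * (qx * qz - qy * qw), 2 * (qy * qz + qx * qw), 1 - 2 * (qx * qx + qy * qy)],
    ])
    t = ref_c - rot @ mob_c
    transform = RigidTransform(rot, t)
    return transform, rmsd(reference, transform.apply(mobile))


def rotation_about_z(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix, det-corrected)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
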