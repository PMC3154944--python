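"""Rigid-body geometry helpers: Kabsch superposition, rotations, angles."""

from __future__ import annotations

import numpy as np


class DegenerateGeometryError(ValueError):
    """Raised when a geometric operation receives degenerate input."""


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(R, t)`` such that ``mobile @ R.T + t`` best fits ``reference``
    in the least-squares sense.  Reflections are excluded (det(R) = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n, 3)")
    if mobile.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 atoms to superpose")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    H = (mobile - cm).T @ (reference - cr)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    # collinearity check: rank of the centred mobile set
    if np.linalg.matrix_rank(mobile - cm, tol=1e-8) < 2:
        raise DegenerateGeometryError("atom set is collinear or degenerate")
    return R, t


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between two matched coordinate sets (Å)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coordinate arrays must have identical shapes")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def angle_to_z(v: np.ndarray) -> float:
    """Angle (degrees, [0, 180]) between a vector and the +z axis."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0 or not np.isfinite(n):
        raise DegenerateGeometryError("zero or non-finite vector")
    c = np.clip(v[2] / n, -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def folded_tilt(v: np.ndarray) -> float:
    """Angle between an (unsigned) axis and z, folded into [0, 90] degrees."""
    a = angle_to_z(v)
    return a if a <= 90.0 else 180.0 - a


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise DegenerateGeometryError("zero rotation axis")
    x, y, z = axis / n
    th = np.radians(angle_deg)
    c, s = np.cos(th), np.sin(th)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


def rotation_between_frames(u1: np.ndarray, u2: np.ndarray,
                            a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation mapping the orthonormal pair (u1, u2) onto (a, b).

    All four vectors are normalised; u2 and b are re-orthogonalised against
    u1 and a respectively so small input deviations do not break rigidity.
    """
    def triad(p, q):
        p = np.asarray(p, float)
        p = p / np.linalg.norm(p)
        q = np.asarray(q, float)
        q = q - (q @ p) * p
        nq = np.linalg.norm(q)
        if nq < 1e-12:
            raise DegenerateGeometryError("frame vectors are parallel")
        q = q / nq
        return np.column_stack([p, q, np.cross(p, q)])

    A = triad(u1, u2)
    B = triad(a, b)
    return B @ A.T


def principal_axis(points: np.ndarray) -> np.ndarray:
    """Dominant principal axis (unit vector) of a point cloud.

    This is the total-least-squares best-fit line direction through the
    centroid.  Sign is arbitrary.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 2:
        raise DegenerateGeometryError("need at least 2 points for an axis")
    centred = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[0] < 1e-12:
        raise DegenerateGeometryError("points are coincident")
    return vt[0]
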