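"""Small rigid-geometry helpers shared across modules.

All coordinates are millimetres. Rotations are 3x3 orthonormal matrices;
a rigid transform is the pair ``(R, t)`` acting as ``x -> R @ x + t``.
"""

from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    """Return v / |v|; raises on a zero vector."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("cannot normalize a zero vector")
    return v / n


def angle_between_deg(a: np.ndarray, b: np.ndarray) -> float:
    """Unsigned angle between two vectors in degrees, numerically safe."""
    c = float(np.dot(unit(a), unit(b)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def rotation_from_axis_angle(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about ``axis`` by ``angle_deg``."""
    k = unit(axis)
    th = np.radians(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation (QR of a Gaussian matrix, sign-fixed)."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def apply_rigid(R: np.ndarray, t: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply ``x -> R x + t`` to an (n, 3) array (or a single point)."""
    pts = np.asarray(points, dtype=float)
    return pts @ np.asarray(R).T + np.asarray(t, dtype=float)


def compose_rigid(R2, t2, R1, t1):
    """Composition (R2,t2) after (R1,t1)."""
    R2, R1 = np.asarray(R2), np.asarray(R1)
    return R2 @ R1, R2 @ np.asarray(t1) + np.asarray(t2)


def invert_rigid(R, t):
    R = np.asarray(R)
    return R.T, -R.T @ np.asarray(t)


def kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best-fit rotation+translation mapping ``src`` onto ``dst`` (least squares).

    Proper rotation only (no reflection), via SVD of the cross-covariance.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, cd - R @ cs
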