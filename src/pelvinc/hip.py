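"""Acetabular sphere fitting and the hip axis.

``fit_sphere`` is an algebraic linear least-squares fit followed by a
geometric (orthogonal-distance) Levenberg-Marquardt refinement.
``fit_acetabulum`` iterates vertex selection around a user seed with an
inlier band around the current sphere surface, which rejects rim and
lunate-margin vertices without any manual trimming.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .surface import SurfaceMesh


@dataclass
class SphereFit:
    center: np.ndarray
    radius: float
    rms_residual: float
    n_inliers: int

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError("fitted radius must be positive")
        if self.n_inliers < 4:
            raise ValueError("a sphere fit needs at least 4 points")


def _algebraic_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    A = np.column_stack([2.0 * points, np.ones(len(points))])
    b = (points**2).sum(axis=1)
    sol, _, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4 or sv[-1] < 1e-9 * sv[0]:
        raise ValueError("points are coplanar or otherwise degenerate for a sphere fit")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise ValueError("degenerate algebraic sphere fit (non-positive radius)")
    return center, float(np.sqrt(r2))


def fit_sphere(points) -> SphereFit:
    """Least-squares sphere through >= 4 non-coplanar points.

    Exact samples of a sphere are recovered to machine precision; noisy data
    get the geometric (orthogonal-distance) optimum.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) < 4:
        raise ValueError("need an (n, 3) array with n >= 4")
    # coplanarity check on the centered cloud
    centered = points - points.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[2] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("points are coplanar; sphere is not identifiable")
    center, radius = _algebraic_sphere(points)

    def residuals(p):
        return np.linalg.norm(points - p[:3], axis=1) - p[3]

    res = least_squares(residuals, np.r_[center, radius], method="lm", xtol=1e-15,
                        ftol=1e-15, gtol=1e-15)
    c, r = res.x[:3], float(res.x[3])
    rms = float(np.sqrt(np.mean(residuals(res.x) ** 2)))
    return SphereFit(center=c, radius=abs(r), rms_residual=rms, n_inliers=len(points))


def fit_acetabulum(
    mesh: SurfaceMesh,
    seed,
    capture_radius: float = 30.0,
    band: float = 0.1,
    max_iter: int = 50,
    tol: float = 1e-6,
    min_inliers: int = 50,
    max_radius: float = 100.0,
    tree: cKDTree | None = None,
) -> SphereFit:
    """Iterative cup fit: capture -> fit -> reselect by surface-distance band.

    Vertices within ``capture_radius`` of the seed initialize the fit; each
    round keeps vertices whose distance to the current sphere surface is
    within ``band * radius`` AND that stay within ``capture_radius`` of the
    seed (so the fit cannot leak onto remote structures), then refits, until
    the center moves less than ``tol`` mm.
    """
    seed = np.asarray(seed, dtype=float)
    tree = tree or cKDTree(mesh.vertices)
    captured = tree.query_ball_point(seed, r=capture_radius)
    if len(captured) < min_inliers:
        raise ValueError(
            f"only {len(captured)} vertices within {capture_radius} mm of the seed; "
            "cup not found"
        )
    captured = np.sort(np.asarray(captured))
    fit = fit_sphere(mesh.vertices[captured])
    for _ in range(max_iter):
        if fit.radius > max_radius:
            break  # reported below; a shell query around a huge sphere is meaningless
        # the band is a thin spherical shell around the current fit, so the
        # reselection is local by construction and independent of the seed
        shell = tree.query_ball_point(fit.center, r=fit.radius * (1.0 + band))
        shell = np.sort(np.asarray(shell))
        local = mesh.vertices[shell]
        dist = np.abs(np.linalg.norm(local - fit.center, axis=1) - fit.radius)
        inliers = local[dist <= band * fit.radius]
        if len(inliers) < min_inliers:
            raise ValueError(
                f"inlier count fell to {len(inliers)} (< {min_inliers}); "
                "the seeded region is not sphere-like"
            )
        new = fit_sphere(inliers)
        shift = float(np.linalg.norm(new.center - fit.center))
        fit = new
        if shift < tol:
            break
    if fit.radius > max_radius:
        raise ValueError(
            f"fitted radius {fit.radius:.1f} mm exceeds {max_radius} mm; the seeded "
            "region is flat or not cup-like"
        )
    if fit.rms_residual > 0.4 * band * fit.radius:
        raise ValueError(
            f"sphere fit rms {fit.rms_residual:.2f} mm is a large fraction of the "
            f"inlier band ({band * fit.radius:.2f} mm); the seeded region is not "
            "sphere-like"
        )
    return fit


def hip_axis(left: SphereFit, right: SphereFit) -> np.ndarray:
    """Midpoint of the segment joining the two fitted sphere centers."""
    return 0.5 * (left.center + right.center)
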