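"""Mid-sagittal plane, sacral-endplate extraction, sagittal line fit, typing.

The mid-sagittal plane starts from the anatomical frame (normal = LR axis,
through the ASIS midpoint) and is refined by mirroring the mesh across the
current plane and registering the mirrored copy onto the original with
point-to-point ICP; the symmetry plane of the composed reflection-plus-rigid
map is extracted and the process repeats until the plane stabilizes.

Endplate points are surface vertices region-grown from a seed, keeping only
upward-facing vertices (normal within a cone of the SUP axis); they are
projected onto the mid-sagittal plane and fitted with an orthogonal
(total-least-squares) line whose endpoints are the extreme projections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .frame import PelvicFrame
from .geometry import kabsch, unit
from .surface import SurfaceMesh


@dataclass
class Plane:
    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if abs(n - 1.0) > 1e-9:
            self.normal = self.normal / n

    def signed_distance(self, points) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.point) @ self.normal

    def project(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts - np.outer(self.signed_distance(pts), self.normal)

    def reflect(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts - 2.0 * np.outer(self.signed_distance(pts), self.normal)


@dataclass
class EndplateProfile:
    """Projected endplate points and their fitted sagittal line segment.

    2D coordinates are (anterior, superior) mm within the mid-sagittal plane.
    """

    points2d: np.ndarray
    line_dir: np.ndarray
    anterior_end: np.ndarray
    posterior_end: np.ndarray
    midpoint: np.ndarray
    n_points: int

    def __post_init__(self) -> None:
        if not np.allclose(
            self.midpoint, 0.5 * (self.anterior_end + self.posterior_end), atol=1e-9
        ):
            raise ValueError("midpoint must be the mean of the two endpoints")
        if not self.anterior_end[0] > self.posterior_end[0]:
            raise ValueError("anterior endpoint must have the larger anterior coordinate")


@dataclass
class EndplateType:
    label: str             # "type1" | "type2" | "flat"
    curvature_coeff: float  # signed quadratic coefficient, 1/mm
    sag_depth: float       # signed extremal deviation from the line, mm


def initial_msp(frame: PelvicFrame, asis_l=None, asis_r=None) -> Plane:
    """Starting mid-sagittal plane: normal = LR, through the ASIS midpoint.

    Falls back to the frame origin when the ASIS points are not supplied.
    """
    if asis_l is not None and asis_r is not None:
        point = 0.5 * (np.asarray(asis_l, dtype=float) + np.asarray(asis_r, dtype=float))
    else:
        point = frame.origin
    return Plane(point=point, normal=frame.lr)


def _plane_from_improper_map(A: np.ndarray, b: np.ndarray, reference: Plane) -> Plane:
    """Symmetry plane of x -> A x + b where A is (close to) a reflection.

    The normal is the eigenvector of A for the eigenvalue nearest -1; a point
    on the plane solves the fixed-point system (A - I) x = -b in the least
    squares sense.
    """
    w, V = np.linalg.eig(A)
    k = int(np.argmin(np.abs(w + 1.0)))
    n = np.real(V[:, k])
    n = unit(n)
    if np.dot(n, reference.normal) < 0:
        n = -n
    x0, *_ = np.linalg.lstsq(A - np.eye(3), -b, rcond=None)
    return Plane(point=x0, normal=n)


def refine_msp_icp(
    mesh: SurfaceMesh,
    initial: Plane,
    max_iter: int = 20,
    tol: float = 1e-3,
    n_subsample: int = 5000,
    icp_iter: int = 30,
    tree: cKDTree | None = None,
) -> Plane:
    """Refine a symmetry plane by mirror-and-register ICP.

    Each outer iteration mirrors a fixed uniform vertex subsample across the
    current plane, runs point-to-point ICP (nearest-neighbour correspondence,
    Kabsch update) against the full vertex set, and extracts the symmetry
    plane of the composed reflection-then-rigid map. Raises if the ICP mean
    closest-point distance increases three times in a row.
    """
    verts = mesh.vertices
    lo, hi = verts.min(axis=0), verts.max(axis=0)
    d_corners = initial.signed_distance(
        np.array([[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1])
                  for z in (lo[2], hi[2])])
    )
    if d_corners.min() > 0 or d_corners.max() < 0:
        raise ValueError("initial plane does not intersect the mesh bounding box")
    tree = tree or cKDTree(verts)
    step = max(1, len(verts) // n_subsample)
    sample = verts[::step]
    plane = Plane(initial.point.copy(), initial.normal.copy())
    for _ in range(max_iter):
        mirrored = plane.reflect(sample)
        moving = mirrored
        R_acc, t_acc = np.eye(3), np.zeros(3)
        prev_err = np.inf
        rises = 0
        for _ in range(icp_iter):
            dist, idx = tree.query(moving)
            err = float(dist.mean())
            if err > prev_err + 1e-12:
                rises += 1
                if rises >= 3:
                    raise RuntimeError(
                        f"ICP diverged: mean closest-point distance rose to {err:.3f} mm "
                        "three iterations in a row"
                    )
            else:
                rises = 0
            R, t = kabsch(moving, verts[idx])
            moving = moving @ R.T + t
            R_acc, t_acc = R @ R_acc, R @ t_acc + t
            if prev_err - err < 1e-7 and np.isfinite(prev_err):
                break
            prev_err = min(prev_err, err)
        # composed map: rigid o reflection
        n = plane.normal
        A = R_acc @ (np.eye(3) - 2.0 * np.outer(n, n))
        b = R_acc @ (2.0 * np.dot(plane.point, n) * n) + t_acc
        new_plane = _plane_from_improper_map(A, b, plane)
        angle = np.arccos(np.clip(abs(np.dot(new_plane.normal, plane.normal)), -1, 1))
        shift = abs(new_plane.signed_distance(plane.point[None])[0])
        plane = new_plane
        if shift + angle * 100.0 < tol:  # plane motion at a 100 mm lever arm
            break
    if np.dot(plane.normal, initial.normal) < 0:
        plane = Plane(plane.point, -plane.normal)
    return plane


def extract_endplate_points(
    mesh: SurfaceMesh,
    seed,
    frame: PelvicFrame,
    n_min: int = 5000,
    n_max: int = 8000,
    max_normal_angle: float = 45.0,
    seed_tolerance: float = 10.0,
    normal_smooth_rounds: int = 4,
) -> np.ndarray:
    """Upward-facing endplate vertices around the seed, count in [n_min, n_max].

    Keeps vertices whose normal lies within ``max_normal_angle`` of SUP,
    takes the connected patch containing the seed, and trims it to the
    ``n_max`` vertices nearest the seed (the adaptive-radius limit). Errors
    if the patch cannot supply ``n_min`` vertices.

    The normal field is averaged over the mesh graph for a few rounds before
    the cone test so that residual voxel staircase does not fragment the
    patch on steeply inclined endplates.
    """
    seed = np.asarray(seed, dtype=float)
    d_seed = np.linalg.norm(mesh.vertices - seed, axis=1)
    if d_seed.min() > seed_tolerance:
        raise ValueError(
            f"seed is {d_seed.min():.1f} mm from the mesh (> {seed_tolerance} mm)"
        )
    adjacency = mesh.vertex_adjacency()
    normals = mesh.vertex_normals
    if normal_smooth_rounds > 0:
        deg = np.asarray(adjacency.sum(axis=1)).ravel() + 1.0
        for _ in range(normal_smooth_rounds):
            normals = (adjacency @ normals + normals) / deg[:, None]
            norms = np.linalg.norm(normals, axis=1)
            norms[norms == 0] = 1.0
            normals = normals / norms[:, None]
    cos_cut = np.cos(np.radians(max_normal_angle))
    upward = normals @ frame.sup > cos_cut
    if not upward.any():
        raise ValueError("no upward-facing vertices under the normal criterion")
    cand = np.flatnonzero(upward)
    sub = adjacency[cand][:, cand]
    n_comp, labels = sparse.csgraph.connected_components(sub, directed=False)
    seed_local = int(np.argmin(d_seed[cand]))
    comp = cand[labels == labels[seed_local]]
    if len(comp) < n_min:
        raise ValueError(
            f"only {len(comp)} connected upward-facing vertices near the seed "
            f"(< {n_min}); increase mesh resolution or relax the point window"
        )
    order = comp[np.argsort(d_seed[comp], kind="stable")]
    return mesh.vertices[order[: min(len(order), n_max)]].copy()


def sagittal_basis(plane: Plane, frame: PelvicFrame):
    """In-plane orthonormal (anterior, superior) basis and its 3D origin."""
    e_a = frame.ant - np.dot(frame.ant, plane.normal) * plane.normal
    e_a = unit(e_a)
    e_s = frame.sup - np.dot(frame.sup, plane.normal) * plane.normal
    e_s = e_s - np.dot(e_s, e_a) * e_a
    e_s = unit(e_s)
    origin = plane.project(frame.origin[None])[0]
    return origin, e_a, e_s


def project_to_plane(points, plane: Plane, frame: PelvicFrame) -> np.ndarray:
    """Orthogonal projection onto the plane, in (anterior, superior) mm."""
    origin, e_a, e_s = sagittal_basis(plane, frame)
    proj = plane.project(points) - origin
    return np.column_stack([proj @ e_a, proj @ e_s])


def fit_endplate_line(points2d, min_axis_ratio: float = 1.5) -> EndplateProfile:
    """Orthogonal least-squares (principal-axis) line through projected points.

    Endpoints are the extreme projections of the data onto the line; the
    midpoint is their mean. The direction is oriented toward anterior.
    """
    pts = np.asarray(points2d, dtype=float)
    if len(pts) < 10:
        raise ValueError("need at least 10 projected points to fit the endplate line")
    mean = pts.mean(axis=0)
    centered = pts - mean
    if not centered.any():
        raise ValueError("all projected points are coincident")
    _, sv, Vt = np.linalg.svd(centered, full_matrices=False)
    if sv[1] > 0 and sv[0] / sv[1] < min_axis_ratio:
        raise ValueError(
            f"projected cloud is nearly isotropic (axis ratio {sv[0] / sv[1]:.2f} "
            f"< {min_axis_ratio}); no line-like structure"
        )
    v = Vt[0]
    if v[0] < 0 or (v[0] == 0 and v[1] < 0):
        v = -v
    t = centered @ v
    anterior = mean + t.max() * v
    posterior = mean + t.min() * v
    return EndplateProfile(
        points2d=pts,
        line_dir=v,
        anterior_end=anterior,
        posterior_end=posterior,
        midpoint=0.5 * (anterior + posterior),
        n_points=len(pts),
    )


def _anterior_perpendicular(line_dir: np.ndarray) -> np.ndarray:
    """In-plane unit perpendicular with a positive anterior component."""
    p = np.array([-line_dir[1], line_dir[0]])
    if p[0] < 0 or (abs(p[0]) < 1e-12 and p[1] < 0):
        p = -p
    return p


def classify_endplate(points2d, profile: EndplateProfile, dead_band: float = 0.5) -> EndplateType:
    """Concavity type from a quadratic fit of residuals along the line.

    Residuals are measured along the perpendicular that points anteriorly, so
    a positive quadratic coefficient means the concave side faces anteriorly
    (type 1) and a negative one posteriorly (type 2); the label falls back to
    "flat" when the extremal deviation stays inside ``dead_band`` mm.
    """
    pts = np.asarray(points2d, dtype=float)
    p = _anterior_perpendicular(profile.line_dir)
    rel = pts - profile.midpoint
    t = rel @ profile.line_dir
    r = rel @ p
    c2, c1, c0 = np.polyfit(t, r, 2)
    t0 = float((profile.posterior_end - profile.midpoint) @ profile.line_dir)
    t1 = float((profile.anterior_end - profile.midpoint) @ profile.line_dir)
    candidates = [t0, t1]
    if c2 != 0.0:
        tv = -c1 / (2.0 * c2)
        if t0 < tv < t1:
            candidates.append(tv)
    q = np.polyval([c2, c1, c0], np.array(candidates))
    sag = float(np.sign(c2) * np.max(np.abs(q))) if c2 != 0 else float(np.max(np.abs(q)))
    if abs(sag) <= dead_band:
        label = "flat"
    else:
        label = "type1" if c2 > 0 else "type2"
    return EndplateType(label=label, curvature_coeff=float(c2), sag_depth=sag)
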