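"""Parametric pelvis phantom with analytically known pelvic incidence.

The phantom lives in an anatomical frame: +x left, +y anterior, +z superior,
mirror-symmetric about the x = 0 plane. It consists of:

* two part-spherical acetabular cups (solid balls of radius ``acetab_radius``),
* a rectangular sacral-endplate shell whose top surface is flat or has a
  circular-arc sagittal section (signed concavity),
* small spherical ASIS / pubic-tubercle prominences whose ventral apexes are
  the exact landmark positions,
* capsule struts that connect everything into one component.

The endplate patch is tilted about the left-right axis so that the angle
between its downward perpendicular at the patch midpoint and the line from
that midpoint to the hip axis equals ``pi_true`` exactly. The tilt is split
between the endplate inclination and the midpoint->hip-axis obliquity via
``hip_obliquity_fraction`` so the endplate never approaches vertical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .geometry import angle_between_deg, unit
from .surface import SurfaceMesh, marching_cubes_field
from .volume_io import CTVolume

_LR = np.array([1.0, 0.0, 0.0])
_ANT = np.array([0.0, 1.0, 0.0])
_SUP = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic pelvis; see module docstring for layout."""

    pi_true: float = 45.0            # degrees
    acetab_radius: float = 24.0      # mm
    acetab_centers: np.ndarray | None = None  # (2, 3) mm; default derived
    endplate_width: float = 70.0     # mm, along left-right
    endplate_depth: float = 62.0     # mm, along the sagittal line
    endplate_concavity: float = 0.0  # signed mm; >0 concave anteriorly (type 1)
    endplate_thickness: float = 12.0
    endplate_center: np.ndarray = field(
        default_factory=lambda: np.array([0.0, -90.0, 110.0])
    )
    asis_positions: np.ndarray = field(
        default_factory=lambda: np.array([[120.0, 0.0, 95.0], [-120.0, 0.0, 95.0]])
    )  # rows: left, right
    pt_positions: np.ndarray = field(
        default_factory=lambda: np.array([[30.0, 0.0, 0.0], [-30.0, 0.0, 0.0]])
    )
    voxel_spacing: tuple = (0.98, 0.98, 1.0)
    noise_sd: float = 0.0            # HU
    bone_hu: float = 700.0
    background_hu: float = -1000.0
    rng_seed: int = 0
    hip_distance: float = 115.0      # |endplate midpoint -> hip axis| when derived
    hip_half_separation: float = 85.0
    hip_obliquity_fraction: float = 0.45  # fraction of pi_true taken up by the
    #                                       midpoint->hip-axis tilt from vertical
    landmark_bump_radius: float = 8.0
    strut_radius: float = 5.0
    mesh_resolution: float = 1.0     # mm, SDF sampling for the mesh route


@dataclass
class PhantomTruth:
    """Exact ground truth for a generated phantom."""

    pi_true: float
    hip_axis: np.ndarray
    endplate_midpoint: np.ndarray
    endplate_direction: np.ndarray  # unit, toward the anterior end
    msp_normal: np.ndarray
    landmarks: dict[str, np.ndarray]
    concavity: float = 0.0

    def transformed(self, R, t) -> "PhantomTruth":
        R = np.asarray(R, dtype=float)
        t = np.asarray(t, dtype=float)
        return PhantomTruth(
            pi_true=self.pi_true,
            hip_axis=R @ self.hip_axis + t,
            endplate_midpoint=R @ self.endplate_midpoint + t,
            endplate_direction=R @ self.endplate_direction,
            msp_normal=R @ self.msp_normal,
            landmarks={k: R @ v + t for k, v in self.landmarks.items()},
            concavity=self.concavity,
        )

    def to_json(self, path: str) -> None:
        payload = {
            "pi_true": self.pi_true,
            "hip_axis": self.hip_axis.tolist(),
            "endplate_midpoint": self.endplate_midpoint.tolist(),
            "endplate_direction": self.endplate_direction.tolist(),
            "msp_normal": self.msp_normal.tolist(),
            "landmarks": {k: v.tolist() for k, v in self.landmarks.items()},
            "concavity": self.concavity,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "PhantomTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            pi_true=d["pi_true"],
            hip_axis=np.array(d["hip_axis"]),
            endplate_midpoint=np.array(d["endplate_midpoint"]),
            endplate_direction=np.array(d["endplate_direction"]),
            msp_normal=np.array(d["msp_normal"]),
            landmarks={k: np.array(v) for k, v in d["landmarks"].items()},
            concavity=d.get("concavity", 0.0),
        )


def pi_from_truth(truth: PhantomTruth) -> float:
    """Closed-form pelvic incidence recomputed from truth fields alone.

    The perpendicular to the endplate line within the symmetry plane is
    ``msp_normal x endplate_direction`` (sign resolved toward the hip axis);
    the PI is its angle to the midpoint->hip-axis direction.
    """
    u = truth.hip_axis - truth.endplate_midpoint
    n = np.cross(truth.msp_normal, truth.endplate_direction)
    if np.dot(n, u) < 0:
        n = -n
    return angle_between_deg(n, u)


# ---------------------------------------------------------------------------
# Geometry resolution


@dataclass
class _Geometry:
    centers: np.ndarray          # (2, 3) cup centers, rows: left, right
    hip_axis: np.ndarray
    midpoint: np.ndarray         # endplate midpoint M
    d: np.ndarray                # sagittal line direction (anterior end)
    n_up: np.ndarray             # upward endplate normal
    slope_deg: float             # endplate inclination from horizontal
    spec: PhantomSpec


def _resolve_geometry(spec: PhantomSpec) -> _Geometry:
    if not 0.0 < spec.pi_true < 90.0:
        raise ValueError(f"pi_true must be in (0, 90) degrees, got {spec.pi_true}")
    if spec.acetab_radius <= 0:
        raise ValueError("acetab_radius must be positive")
    if np.any(np.asarray(spec.voxel_spacing) <= 0):
        raise ValueError("voxel_spacing must be strictly positive")
    if min(spec.endplate_width, spec.endplate_depth, spec.endplate_thickness) <= 0:
        raise ValueError("endplate dimensions must be positive")

    M = np.asarray(spec.endplate_center, dtype=float)
    if spec.acetab_centers is not None:
        centers = np.asarray(spec.acetab_centers, dtype=float).reshape(2, 3)
        if np.linalg.norm(centers[0] - centers[1]) <= 2 * spec.acetab_radius:
            raise ValueError("acetabular cups overlap each other")
        hip = centers.mean(axis=0)
        u = unit(hip - M)
        obliquity = np.degrees(np.arctan2(u[1], -u[2]))
    else:
        obliquity = spec.hip_obliquity_fraction * spec.pi_true
        phi = np.radians(obliquity)
        hip = M + spec.hip_distance * np.array([0.0, np.sin(phi), -np.cos(phi)])
        centers = np.vstack(
            [hip + spec.hip_half_separation * _LR, hip - spec.hip_half_separation * _LR]
        )

    slope = spec.pi_true - obliquity  # endplate inclination from horizontal
    if not 1.0 <= slope <= 44.0:
        raise ValueError(
            f"endplate inclination {slope:.1f} deg is outside the buildable range "
            "[1, 44] deg (the upward-normal extraction window is 45 deg); adjust "
            "pi_true, hip placement, or hip_obliquity_fraction"
        )
    ss = np.radians(slope)
    n_up = np.array([0.0, np.sin(ss), np.cos(ss)])
    d = np.array([0.0, np.cos(ss), -np.sin(ss)])

    half_diag = 0.5 * float(np.hypot(spec.endplate_depth, spec.endplate_width))
    clearance = np.linalg.norm(centers - M, axis=1) - (spec.acetab_radius + half_diag)
    if np.any(clearance < 5.0):
        raise ValueError(
            "acetabular cups overlap the endplate patch "
            f"(clearance {clearance.min():.1f} mm < 5 mm)"
        )
    return _Geometry(centers, hip, M, d, n_up, slope, spec)


def _make_truth(g: _Geometry) -> PhantomTruth:
    spec = g.spec
    R = spec.acetab_radius
    delta = spec.endplate_concavity
    seed = g.midpoint - (delta / 3.0) * g.n_up  # on the (possibly curved) surface
    landmarks = {
        "ASIS_L": spec.asis_positions[0].astype(float),
        "ASIS_R": spec.asis_positions[1].astype(float),
        "PT_L": spec.pt_positions[0].astype(float),
        "PT_R": spec.pt_positions[1].astype(float),
        "acetab_seed_L": g.centers[0] + R * _LR,
        "acetab_seed_R": g.centers[1] - R * _LR,
        "endplate_seed": seed,
    }
    return PhantomTruth(
        pi_true=spec.pi_true,
        hip_axis=g.hip_axis.copy(),
        endplate_midpoint=g.midpoint.copy(),
        endplate_direction=g.d.copy(),
        msp_normal=np.array([1.0, 0.0, 0.0]),
        landmarks=landmarks,
        concavity=delta,
    )


# ---------------------------------------------------------------------------
# Signed-distance construction


def _sphere_sdf(X, Y, Z, c, r):
    c = [float(v) for v in c]
    return np.sqrt((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2) - float(r)


def _capsule_sdf(X, Y, Z, a, b, r):
    a = np.asarray(a, dtype=float)
    v = np.asarray(b, dtype=float) - a
    vv = float(v @ v)
    t = ((X - float(a[0])) * float(v[0] / vv)
         + (Y - float(a[1])) * float(v[1] / vv)
         + (Z - float(a[2])) * float(v[2] / vv))
    np.clip(t, 0.0, 1.0, out=t)
    dx = X - float(a[0]) - t * float(v[0])
    dy = Y - float(a[1]) - t * float(v[1])
    dz = Z - float(a[2]) - t * float(v[2])
    return np.sqrt(dx * dx + dy * dy + dz * dz) - float(r)


def _slab_sdf(X, Y, Z, g: _Geometry):
    """Endplate shell: box in patch coordinates with a curved top face.

    The top surface along the sagittal coordinate xi is offset
    ``f(xi) = delta * ((2 xi / L)^2 - 1/3)`` along the upward normal, which
    makes the orthogonal-regression line of the surface coincide with the
    chord through the midpoint (the f mean over the patch is zero).
    """
    spec = g.spec
    M = [float(v) for v in g.midpoint]
    d = [float(v) for v in g.d]
    n_up = [float(v) for v in g.n_up]
    L, W, T = float(spec.endplate_depth), float(spec.endplate_width), float(spec.endplate_thickness)
    delta = float(spec.endplate_concavity)
    xi = (X - M[0]) * d[0] + (Y - M[1]) * d[1] + (Z - M[2]) * d[2]
    eta = X - M[0]  # left-right coordinate (d and n_up have zero x-component)
    zeta = (X - M[0]) * n_up[0] + (Y - M[1]) * n_up[1] + (Z - M[2]) * n_up[2]
    f = delta * ((2.0 * xi / L) ** 2 - 1.0 / 3.0)
    sdf = np.abs(xi) - L / 2.0
    np.maximum(sdf, np.abs(eta) - W / 2.0, out=sdf)
    np.maximum(sdf, zeta - f, out=sdf)
    np.maximum(sdf, (f - T) - zeta, out=sdf)
    return sdf


def _primitives(g: _Geometry):
    """List of (kind, params) solids; used by both SDF evaluation and bbox."""
    spec = g.spec
    rb = spec.landmark_bump_radius
    rs = spec.strut_radius
    bumps = [p - rb * _ANT for p in spec.asis_positions] + [
        p - rb * _ANT for p in spec.pt_positions
    ]
    strut_r = min(rs, rb / 2.0)
    prims = [
        ("sphere", (g.centers[0], spec.acetab_radius)),
        ("sphere", (g.centers[1], spec.acetab_radius)),
        ("slab", None),
    ]
    prims += [("sphere", (b, rb)) for b in bumps]
    # connectivity: hip bar, endplate strut, struts to each landmark bump
    under = g.midpoint - 15.0 * g.n_up
    prims.append(("capsule", (g.centers[1], g.centers[0], rs)))
    prims.append(("capsule", (g.hip_axis, under, rs)))
    for i, b in enumerate(bumps):
        c = g.centers[0] if b[0] >= 0 else g.centers[1]
        prims.append(("capsule", (c, b, strut_r)))
    return prims


def _primitive_bbox(kind, params, g: _Geometry) -> tuple[np.ndarray, np.ndarray]:
    spec = g.spec
    if kind == "sphere":
        c, r = params
        return c - r, c + r
    if kind == "capsule":
        a, b, r = params
        lo = np.minimum(a, b) - r
        return lo, np.maximum(a, b) + r
    L, W = spec.endplate_depth, spec.endplate_width
    T, delta = spec.endplate_thickness, abs(spec.endplate_concavity)
    corners = [
        g.midpoint + sx * (L / 2) * g.d + se * (W / 2) * _LR + sz * g.n_up
        for sx in (-1, 1)
        for se in (-1, 1)
        for sz in (-T - delta, delta)
    ]
    corners = np.array(corners)
    return corners.min(axis=0), corners.max(axis=0)


def _bbox(g: _Geometry, margin: float = 6.0) -> tuple[np.ndarray, np.ndarray]:
    boxes = [_primitive_bbox(k, p, g) for k, p in _primitives(g)]
    lo = np.min([b[0] for b in boxes], axis=0) - margin
    hi = np.max([b[1] for b in boxes], axis=0) + margin
    return lo, hi


def _eval_sdf_grid(xs, ys, zs, g: _Geometry, far: float = 1e4) -> np.ndarray:
    """Union SDF sampled on the grid ``xs x ys x zs``.

    Each primitive is evaluated only inside its padded bounding box (open-grid
    broadcasting), so values far from every solid are a constant positive
    ``far`` — exact near every surface, which is all that voxelization and
    marching cubes require.
    """
    steps = np.array([xs[1] - xs[0] if len(xs) > 1 else 1.0,
                      ys[1] - ys[0] if len(ys) > 1 else 1.0,
                      zs[1] - zs[0] if len(zs) > 1 else 1.0])
    pad = 4.0 * steps
    grid0 = np.array([xs[0], ys[0], zs[0]])
    shape = (len(xs), len(ys), len(zs))
    field = np.full(shape, np.float32(far), dtype=np.float32)
    for kind, params in _primitives(g):
        lo, hi = _primitive_bbox(kind, params, g)
        i0 = np.maximum(np.floor((lo - pad - grid0) / steps).astype(int), 0)
        i1 = np.minimum(
            np.ceil((hi + pad - grid0) / steps).astype(int) + 1, np.array(shape)
        )
        if np.any(i0 >= i1):
            continue
        X = xs[i0[0]:i1[0], None, None]
        Y = ys[None, i0[1]:i1[1], None]
        Z = zs[None, None, i0[2]:i1[2]]
        if kind == "sphere":
            d = _sphere_sdf(X, Y, Z, *params)
        elif kind == "capsule":
            d = _capsule_sdf(X, Y, Z, *params)
        else:
            d = _slab_sdf(X, Y, Z, g)
        sub = field[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
        np.minimum(sub, d.astype(np.float32), out=sub)
    return field


def _axes(lo, hi, steps) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    steps = np.broadcast_to(np.asarray(steps, dtype=float), (3,))
    n = np.ceil((hi - lo) / steps).astype(int) + 1
    return tuple(
        (lo[m] + steps[m] * np.arange(n[m])).astype(np.float32) for m in range(3)
    )


def analytic_solid_volume(spec: PhantomSpec, resolution: float = 0.4) -> float:
    """Reference solid volume (mm^3) by fine SDF quadrature.

    Independent of the voxel/threshold route: evaluates the generative signed
    distance on a grid much finer than the CT spacing.
    """
    g = _resolve_geometry(spec)
    lo, hi = _bbox(g, margin=2.0)
    xs, ys, zs = _axes(lo, hi, resolution)
    field = _eval_sdf_grid(xs, ys, zs, g)
    return float((field <= 0).sum()) * resolution**3


def generate_phantom_mesh(spec: PhantomSpec) -> tuple[SurfaceMesh, PhantomTruth]:
    """Triangle-mesh phantom via marching cubes on the signed distance field."""
    g = _resolve_geometry(spec)
    res = spec.mesh_resolution
    lo, hi = _bbox(g)
    xs, ys, zs = _axes(lo, hi, res)
    sdf = _eval_sdf_grid(xs, ys, zs, g)
    mesh = marching_cubes_field(sdf, 0.0, (res, res, res), lo)
    return mesh, _make_truth(g)


def generate_phantom_volume(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Voxelized phantom: bone_hu inside, background_hu outside, optional noise.

    Voxelization samples the signed distance at voxel centers (no
    anti-aliasing) so the result is deterministic; noise is seeded Gaussian.
    """
    g = _resolve_geometry(spec)
    spacing = np.asarray(spec.voxel_spacing, dtype=float)
    if 2.0 * spec.acetab_radius / spacing.max() < 5.0:
        raise ValueError(
            f"voxel spacing {spacing} too coarse: an acetabular cup would span "
            "fewer than 5 voxels"
        )
    lo, hi = _bbox(g)
    xs, ys, zs = _axes(lo, hi, spacing)
    inside = _eval_sdf_grid(xs, ys, zs, g) <= 0
    voxels = np.where(inside, np.float32(spec.bone_hu), np.float32(spec.background_hu))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        voxels = voxels + rng.normal(0.0, spec.noise_sd, voxels.shape).astype(np.float32)
    vol = CTVolume(voxels=voxels, spacing=spacing, origin=lo, orientation=np.eye(3))
    return vol, _make_truth(g)


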