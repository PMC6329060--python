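"""Shared fixtures: session-scoped phantoms and small synthetic meshes."""

from __future__ import annotations

import numpy as np
import pytest

from pelvinc.frame import LandmarkSet
from pelvinc.phantom import PhantomSpec, generate_phantom_mesh, generate_phantom_volume
from pelvinc.segmentation import BinaryMask
from pelvinc.surface import SurfaceMesh


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec(pi_true=45.0)


@pytest.fixture(scope="session")
def phantom_mesh(default_spec):
    return generate_phantom_mesh(default_spec)


@pytest.fixture(scope="session")
def phantom_volume(default_spec):
    return generate_phantom_volume(default_spec)


@pytest.fixture(scope="session")
def phantom_landmarks(phantom_mesh) -> LandmarkSet:
    _, truth = phantom_mesh
    return LandmarkSet.from_truth(truth)


def make_sphere_mask(radius_mm: float, spacing, center=None, pad: float = 4.0) -> BinaryMask:
    """Voxelized ball for surface/segmentation tests."""
    spacing = np.asarray(spacing, dtype=float)
    if center is None:
        center = np.zeros(3)
    center = np.asarray(center, dtype=float)
    lo = center - radius_mm - pad
    n = np.ceil((2 * (radius_mm + pad)) / spacing).astype(int) + 1
    axes = [lo[m] + spacing[m] * np.arange(n[m]) for m in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    inside = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2 <= radius_mm**2
    return BinaryMask(inside, spacing, lo, np.eye(3))


def make_bump_mesh(
    bump_center=(0.0, 0.0), bump_radius: float = 8.0, bump_height: float = 8.0,
    extent: float = 30.0, step: float = 0.5,
) -> SurfaceMesh:
    """Height-field mesh: flat plane y=0 with a spherical-cap bump toward +y.

    The apex vertex (max anterior coordinate) is analytically at
    (bump_center[0], bump_height, bump_center[1]).
    """
    xs = np.arange(-extent, extent + step / 2, step)
    zs = np.arange(-extent, extent + step / 2, step)
    X, Z = np.meshgrid(xs, zs, indexing="ij")
    r2 = (X - bump_center[0]) ** 2 + (Z - bump_center[1]) ** 2
    cap_r2 = bump_radius**2
    sphere_c_y = bump_height - bump_radius  # sphere center below the apex
    Y = np.where(r2 < cap_r2, sphere_c_y + np.sqrt(np.maximum(cap_r2 - r2, 0.0)), 0.0)
    Y = np.maximum(Y, 0.0)
    nx, nz = X.shape
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    idx = np.arange(nx * nz).reshape(nx, nz)
    a, b, c, d = idx[:-1, :-1], idx[1:, :-1], idx[:-1, 1:], idx[1:, 1:]
    faces = np.concatenate(
        [np.stack([a, b, d], axis=-1).reshape(-1, 3),
         np.stack([a, d, c], axis=-1).reshape(-1, 3)]
    )
    return SurfaceMesh(verts, faces)


def fibonacci_sphere(n: int, center, radius: float, hemisphere: bool = False) -> np.ndarray:
    """Deterministic quasi-uniform samples on a sphere (or upper hemisphere)."""
    i = np.arange(n, dtype=float)
    golden = (1 + 5**0.5) / 2
    z = 1 - (2 * i + 1) / n
    if hemisphere:
        z = np.abs(z)
    theta = 2 * np.pi * i / golden
    r_xy = np.sqrt(np.maximum(0.0, 1 - z * z))
    pts = np.column_stack([r_xy * np.cos(theta), r_xy * np.sin(theta), z])
    return np.asarray(center, dtype=float) + radius * pts
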