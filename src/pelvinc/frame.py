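"""Anterior-pelvic-plane landmarks, anatomical frame, and pose alignment.

The APP is the plane through both ASIS points and the midpoint of the two
pubic tubercles. The anatomical frame is: LR (right ASIS -> left ASIS),
ANT (ventral APP normal), SUP = LR x ANT. Landmark seeds are refined to the
locally most ventral mesh vertex by a fixed-point iteration; the frame and
the refinement are iterated together until both stabilize.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import unit
from .surface import SurfaceMesh

LANDMARK_NAMES = (
    "ASIS_L",
    "ASIS_R",
    "PT_L",
    "PT_R",
    "acetab_seed_L",
    "acetab_seed_R",
    "endplate_seed",
)


@dataclass
class LandmarkSet:
    """Named 3D points (mm) in the mesh frame."""

    points: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.points = {k: np.asarray(v, dtype=float) for k, v in self.points.items()}
        for name in LANDMARK_NAMES:
            if name not in self.points:
                raise ValueError(f"missing landmark {name!r}; required: {LANDMARK_NAMES}")
        if np.allclose(self["ASIS_L"], self["ASIS_R"]):
            raise ValueError("ASIS_L and ASIS_R must be distinct points")
        if np.allclose(self["PT_L"], self["PT_R"]):
            raise ValueError("PT_L and PT_R must be distinct points")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def transformed(self, R, t) -> "LandmarkSet":
        R = np.asarray(R, dtype=float)
        t = np.asarray(t, dtype=float)
        return LandmarkSet({k: R @ v + t for k, v in self.points.items()})

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({k: v.tolist() for k, v in self.points.items()}, fh,
                      indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "LandmarkSet":
        with open(path) as fh:
            return cls(points=json.load(fh))

    @classmethod
    def from_truth(cls, truth) -> "LandmarkSet":
        return cls(points={k: v.copy() for k, v in truth.landmarks.items()})


@dataclass
class PelvicFrame:
    """Right-handed orthonormal anatomical frame; origin at the PT midpoint."""

    origin: np.ndarray
    lr: np.ndarray
    ant: np.ndarray
    sup: np.ndarray

    def __post_init__(self) -> None:
        for name in ("lr", "ant", "sup"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError(f"{name} axis is not unit length")
        if np.linalg.norm(np.cross(self.lr, self.ant) - self.sup) > 1e-9:
            raise ValueError("frame is not right-handed orthonormal (lr x ant != sup)")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def rotation(self) -> np.ndarray:
        """Rows LR/ANT/SUP: maps world vectors to frame coordinates."""
        return np.vstack([self.lr, self.ant, self.sup])

    def to_frame(self, points) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.origin) @ self.rotation.T


def compute_app(asis_l, asis_r, pt_l, pt_r) -> PelvicFrame:
    """Anatomical frame from the four APP landmarks.

    The APP passes through ASIS_L, ASIS_R and the PT midpoint. ANT is the
    APP normal signed so that SUP = LR x ANT points from the PT midpoint
    toward the ASIS midpoint (cranially).
    """
    asis_l = np.asarray(asis_l, dtype=float)
    asis_r = np.asarray(asis_r, dtype=float)
    pt_mid = 0.5 * (np.asarray(pt_l, dtype=float) + np.asarray(pt_r, dtype=float))
    n = np.cross(asis_l - pt_mid, asis_r - pt_mid)
    if np.linalg.norm(n) < 1e-9 * max(
        np.linalg.norm(asis_l - pt_mid), np.linalg.norm(asis_r - pt_mid), 1.0
    ):
        raise ValueError("ASIS_L, ASIS_R and the PT midpoint are collinear")
    n = unit(n)
    lr = unit(asis_l - asis_r)  # lies in the APP by construction
    up_hint = 0.5 * (asis_l + asis_r) - pt_mid
    ant = n if np.dot(np.cross(lr, n), up_hint) > 0 else -n
    sup = np.cross(lr, ant)
    return PelvicFrame(origin=pt_mid, lr=lr, ant=ant, sup=sup / np.linalg.norm(sup))


def refine_landmark_ventral(
    mesh: SurfaceMesh,
    seed,
    frame: PelvicFrame,
    radius: float = 10.0,
    tree: cKDTree | None = None,
    max_iter: int = 100,
) -> np.ndarray:
    """Locally most ventral vertex: fixed point of "argmax ANT within radius".

    Deterministic tie-break: the lowest vertex index among equal maxima.
    The iteration terminates because the ANT coordinate is non-decreasing
    over a finite vertex set.
    """
    tree = tree or cKDTree(mesh.vertices)
    ant_coord = mesh.vertices @ frame.ant
    estimate = np.asarray(seed, dtype=float)
    current = -1
    for _ in range(max_iter):
        idx = tree.query_ball_point(estimate, r=radius)
        if not idx:
            raise ValueError(
                f"no mesh vertices within {radius} mm of seed {estimate}"
            )
        idx = np.sort(np.asarray(idx))
        best = idx[int(np.argmax(ant_coord[idx]))]  # argmax takes first max
        if best == current:
            break
        current = best
        estimate = mesh.vertices[best]
    return mesh.vertices[current].copy()


def refine_landmarks(
    mesh: SurfaceMesh,
    landmarks: LandmarkSet,
    radius: float = 10.0,
    max_rounds: int = 5,
    tol: float = 1e-3,
) -> tuple[LandmarkSet, PelvicFrame]:
    """Refine the four APP landmarks and rebuild the frame to convergence.

    The initial frame is bootstrapped from the unrefined seeds; each round
    refines ASIS/PT points to their locally most ventral vertices under the
    current frame and recomputes the APP, stopping when no landmark moves
    more than ``tol`` mm (at most ``max_rounds`` rounds).
    """
    tree = cKDTree(mesh.vertices)
    pts = dict(landmarks.points)
    frame = compute_app(pts["ASIS_L"], pts["ASIS_R"], pts["PT_L"], pts["PT_R"])
    for _ in range(max_rounds):
        moved = 0.0
        for name in ("ASIS_L", "ASIS_R", "PT_L", "PT_R"):
            new = refine_landmark_ventral(mesh, pts[name], frame, radius, tree=tree)
            moved = max(moved, float(np.linalg.norm(new - pts[name])))
            pts[name] = new
        frame = compute_app(pts["ASIS_L"], pts["ASIS_R"], pts["PT_L"], pts["PT_R"])
        if moved < tol:
            break
    return LandmarkSet(points=pts), frame


def align_to_app(
    mesh: SurfaceMesh, frame: PelvicFrame
) -> tuple[SurfaceMesh, tuple[np.ndarray, np.ndarray]]:
    """Pose the mesh so LR -> +x, ANT -> +y, SUP -> +z, PT midpoint -> origin.

    The APP becomes the world x-z plane, perpendicular to the horizontal
    (x-y) plane. Returns the aligned mesh and the rigid transform (R, t)
    that was applied (x' = R x + t).
    """
    R = frame.rotation
    t = -R @ frame.origin
    return mesh.transformed(R, t), (R, t)


CANONICAL_FRAME = PelvicFrame(
    origin=np.zeros(3),
    lr=np.array([1.0, 0.0, 0.0]),
    ant=np.array([0.0, 1.0, 0.0]),
    sup=np.array([0.0, 0.0, 1.0]),
)
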