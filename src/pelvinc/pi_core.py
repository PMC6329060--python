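"""Pelvic-incidence angle and the end-to-end measurement pipeline.

PI is the angle between the in-plane perpendicular to the sacral-endplate
line at its midpoint (oriented toward the hip axis) and the line from that
midpoint to the hip axis projected into the mid-sagittal plane. It is an
anatomical parameter: the pipeline removes pose via APP alignment before
anything is measured, and the reported angle is unsigned in (0, 90).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import endplate as ep
from . import frame as fr
from . import hip as hp
from . import segmentation as seg
from . import surface as sf
from .volume_io import CTVolume

# observed cohort range used only as a plausibility flag, never as a constraint
PLAUSIBLE_PI_RANGE = (30.49, 70.12)


@dataclass(frozen=True)
class PipelineConfig:
    """Every tolerance and iteration cap in one place, serialized for provenance."""

    hu_low: float = 200.0
    hu_high: float = float("inf")
    body_seed: tuple | None = None        # mm; default: midpoint of acetabular seeds
    removal_seeds: tuple = ()             # mm points whose components are deleted
    smooth_iterations: int = 10
    smooth_lambda: float = 0.5
    smooth_mu: float = -0.53
    landmark_radius: float = 10.0
    landmark_rounds: int = 5
    capture_radius: float = 30.0
    band: float = 0.1
    msp_max_iter: int = 20
    msp_tol: float = 1e-3
    icp_subsample: int = 5000
    endplate_n_min: int = 5000
    endplate_n_max: int = 8000
    endplate_max_normal_angle: float = 45.0
    dead_band: float = 0.5

    def to_dict(self) -> dict:
        d = asdict(self)
        d["removal_seeds"] = [list(map(float, s)) for s in self.removal_seeds]
        if self.body_seed is not None:
            d["body_seed"] = list(map(float, self.body_seed))
        return d


@dataclass
class PIResult:
    pi: float
    flagged: bool
    hip_axis_2d: np.ndarray
    endplate_midpoint_2d: np.ndarray
    endplate_direction_2d: np.ndarray
    msp: ep.Plane
    sphere_left: hp.SphereFit
    sphere_right: hp.SphereFit
    endplate_type: ep.EndplateType
    diagnostics: dict
    config: PipelineConfig
    profile: ep.EndplateProfile | None = field(default=None, repr=False)
    aligned_mesh: sf.SurfaceMesh | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "pi_deg": self.pi,
            "flagged_outside_plausible_range": self.flagged,
            "plausible_range_deg": list(PLAUSIBLE_PI_RANGE),
            "hip_axis_2d_mm": self.hip_axis_2d.tolist(),
            "endplate_midpoint_2d_mm": self.endplate_midpoint_2d.tolist(),
            "endplate_direction_2d": self.endplate_direction_2d.tolist(),
            "msp": {
                "point_mm": self.msp.point.tolist(),
                "normal": self.msp.normal.tolist(),
            },
            "sphere_left": _sphere_dict(self.sphere_left),
            "sphere_right": _sphere_dict(self.sphere_right),
            "endplate_type": {
                "label": self.endplate_type.label,
                "curvature_coeff_per_mm": self.endplate_type.curvature_coeff,
                "sag_depth_mm": self.endplate_type.sag_depth,
            },
            "diagnostics": self.diagnostics,
            "config": self.config.to_dict(),
            "schema_version": 1,
        }

    def to_json(self, path: str | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _sphere_dict(s: hp.SphereFit) -> dict:
    return {
        "center_mm": s.center.tolist(),
        "radius_mm": s.radius,
        "rms_residual_mm": s.rms_residual,
        "n_inliers": s.n_inliers,
    }


def compute_pi(
    profile: ep.EndplateProfile,
    hip_axis_point,
    msp: ep.Plane,
    frame: fr.PelvicFrame,
) -> float:
    """PI in degrees from a fitted endplate profile and the 3D hip axis.

    The hip axis is projected into the mid-sagittal plane; the endplate
    perpendicular is oriented toward the hip-axis side before the angle is
    taken, so the result is unsigned.
    """
    hip2d = ep.project_to_plane(np.asarray(hip_axis_point, dtype=float)[None], msp, frame)[0]
    v = hip2d - profile.midpoint
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise ValueError("hip axis projects onto the endplate midpoint; PI undefined")
    v = v / norm
    n = np.array([-profile.line_dir[1], profile.line_dir[0]])
    if np.dot(n, v) < 0:
        n = -n
    return float(np.degrees(np.arccos(np.clip(np.dot(n, v), -1.0, 1.0))))


class PipelineError(RuntimeError):
    """Stage failure with the stage name and a remediation hint."""

    def __init__(self, stage: str, original: Exception, hint: str):
        super().__init__(f"[{stage}] {original} — {hint}")
        self.stage = stage
        self.original = original


def _stage(stage: str, hint: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except (ValueError, RuntimeError) as exc:
        raise PipelineError(stage, exc, hint) from exc


def segment_and_reconstruct(
    vol: CTVolume, landmarks: fr.LandmarkSet, config: PipelineConfig
) -> tuple[sf.SurfaceMesh, dict]:
    """Threshold + region-grow the bone, then reconstruct and smooth the surface."""
    diag: dict = {}
    mask = _stage("threshold", "check hu_low/hu_high against the scan",
                  seg.threshold_mask, vol, config.hu_low, config.hu_high)
    diag["threshold_voxels"] = int(mask.voxels.sum())
    body_seed = config.body_seed
    if body_seed is None:
        body_seed = 0.5 * (landmarks["acetab_seed_L"] + landmarks["acetab_seed_R"])
    try:
        mask = seg.region_grow(mask, body_seed)
    except ValueError:
        # seed in soft tissue (e.g. the hip-axis midpoint on a real pelvis):
        # keep the largest connected component instead
        from scipy import ndimage

        labels, n = ndimage.label(mask.voxels, structure=np.ones((3, 3, 3), bool))
        if n == 0:
            raise PipelineError(
                "region_grow", ValueError("empty threshold mask"),
                "lower hu_low or verify the volume is in HU",
            ) from None
        counts = np.bincount(labels.ravel())[1:]
        keep = labels == (1 + int(np.argmax(counts)))
        mask = seg.BinaryMask(keep, mask.spacing, mask.origin, mask.orientation)
        diag["region_grow_fallback"] = "largest_component"
    for seed in config.removal_seeds:
        mask = _stage("remove_component", "removal seed must lie on segmented bone",
                      seg.remove_component, mask, np.asarray(seed, dtype=float))
    diag["segmented_voxels"] = int(mask.voxels.sum())
    mesh = _stage("isosurface", "segmentation produced an empty mask",
                  sf.extract_isosurface, mask)
    mesh = sf.smooth_mesh(mesh, config.smooth_iterations,
                          config.smooth_lambda, config.smooth_mu)
    diag["mesh_vertices"] = mesh.n_vertices
    diag["mesh_faces"] = mesh.n_faces
    return mesh, diag


def measure_pi_pipeline(
    data: CTVolume | sf.SurfaceMesh,
    landmarks: fr.LandmarkSet,
    config: PipelineConfig | None = None,
) -> PIResult:
    """Full measurement: segmentation -> surface -> frame -> hip -> endplate -> PI.

    ``data`` may be a CT volume or an already reconstructed mesh (the mesh
    route skips segmentation and smoothing). Deterministic for fixed inputs.
    """
    config = config or PipelineConfig()
    diag: dict = {}
    if isinstance(data, CTVolume):
        mesh, seg_diag = segment_and_reconstruct(data, landmarks, config)
        diag.update(seg_diag)
        diag["input"] = "volume"
    else:
        mesh = data
        diag["input"] = "mesh"
        diag["mesh_vertices"] = mesh.n_vertices

    refined, frame = _stage(
        "frame", "check that ASIS/PT seeds are within ~10 mm of the bony landmarks",
        fr.refine_landmarks, mesh, landmarks,
        radius=config.landmark_radius, max_rounds=config.landmark_rounds,
    )
    mesh, (R, t) = fr.align_to_app(mesh, frame)
    refined = refined.transformed(R, t)
    frame = fr.CANONICAL_FRAME
    diag["alignment_rotation"] = np.asarray(R).tolist()
    diag["alignment_translation"] = np.asarray(t).tolist()

    tree = cKDTree(mesh.vertices)
    fit_l = _stage("hip", "move the acetabular seed into the cup",
                   hp.fit_acetabulum, mesh, refined["acetab_seed_L"],
                   config.capture_radius, config.band, tree=tree)
    fit_r = _stage("hip", "move the acetabular seed into the cup",
                   hp.fit_acetabulum, mesh, refined["acetab_seed_R"],
                   config.capture_radius, config.band, tree=tree)
    hip_point = hp.hip_axis(fit_l, fit_r)

    msp0 = ep.initial_msp(frame, refined["ASIS_L"], refined["ASIS_R"])
    msp = _stage("msp", "mesh may lack left-right symmetry; check segmentation",
                 ep.refine_msp_icp, mesh, msp0,
                 max_iter=config.msp_max_iter, tol=config.msp_tol,
                 n_subsample=config.icp_subsample, tree=tree)

    points3d = _stage(
        "endplate", "check the endplate seed and the mesh resolution",
        ep.extract_endplate_points, mesh, refined["endplate_seed"], frame,
        n_min=config.endplate_n_min, n_max=config.endplate_n_max,
        max_normal_angle=config.endplate_max_normal_angle,
    )
    pts2d = ep.project_to_plane(points3d, msp, frame)
    profile = _stage("endplate_fit", "endplate patch is not line-like in the sagittal plane",
                     ep.fit_endplate_line, pts2d)
    etype = ep.classify_endplate(pts2d, profile, dead_band=config.dead_band)
    pi = _stage("pi", "hip axis coincides with the endplate midpoint",
                compute_pi, profile, hip_point, msp, frame)

    diag["endplate_points"] = int(profile.n_points)
    diag["sphere_rms_mm"] = [fit_l.rms_residual, fit_r.rms_residual]
    diag["msp_point_mm"] = msp.point.tolist()
    diag["msp_normal"] = msp.normal.tolist()
    hip2d = ep.project_to_plane(np.asarray(hip_point)[None], msp, frame)[0]
    return PIResult(
        pi=pi,
        flagged=not PLAUSIBLE_PI_RANGE[0] <= pi <= PLAUSIBLE_PI_RANGE[1],
        hip_axis_2d=hip2d,
        endplate_midpoint_2d=profile.midpoint,
        endplate_direction_2d=profile.line_dir,
        msp=msp,
        sphere_left=fit_l,
        sphere_right=fit_r,
        endplate_type=etype,
        diagnostics=diag,
        config=config,
        profile=profile,
        aligned_mesh=mesh,
    )
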