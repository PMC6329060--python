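"""Canonical HU volume container and research-format I/O (NIfTI, NRRD).

The canonical patient coordinate convention is LPS (DICOM native): +x left,
+y posterior, +z superior in scanner space. Anatomical axes used downstream
are derived from landmarks, so this choice only affects I/O. Voxel indices
are 0-based and physical points refer to voxel centers:

    physical = origin + orientation @ (spacing * index)
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np


@dataclass
class CTVolume:
    """HU voxel grid with physical geometry.

    ``voxels`` is indexed ``[i, j, k]``; column ``m`` of ``orientation``
    is the unit patient-space direction of increasing index ``m``.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D volume, got {self.voxels.ndim}D")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if abs(abs(np.linalg.det(self.orientation)) - 1.0) > 1e-6:
            raise ValueError("orientation must be orthonormal (|det| = 1)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def affine(self) -> np.ndarray:
        """4x4 index->physical affine (LPS)."""
        A = np.eye(4)
        A[:3, :3] = self.orientation * self.spacing
        A[:3, 3] = self.origin
        return A

    def index_to_physical(self, index) -> np.ndarray:
        idx = np.asarray(index, dtype=float)
        return idx @ (self.orientation * self.spacing).T + self.origin

    def physical_to_index(self, point) -> np.ndarray:
        p = np.asarray(point, dtype=float) - self.origin
        return p @ np.linalg.inv(self.orientation * self.spacing).T

    def physical_to_nearest_voxel(self, point) -> tuple[int, int, int]:
        idx = np.rint(self.physical_to_index(point)).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(self.shape)):
            raise ValueError(f"point {np.asarray(point)} maps outside the grid (index {idx})")
        return tuple(int(v) for v in idx)


# NIfTI stores RAS affines; our canonical frame is LPS.
_RAS_TO_LPS = np.diag([-1.0, -1.0, 1.0, 1.0])


def _volume_from_lps_affine(data: np.ndarray, affine_lps: np.ndarray) -> CTVolume:
    M = affine_lps[:3, :3]
    spacing = np.linalg.norm(M, axis=0)
    return CTVolume(
        voxels=data,
        spacing=spacing,
        origin=affine_lps[:3, 3].copy(),
        orientation=M / spacing,
    )


def read_volume(path: str | os.PathLike) -> CTVolume:
    """Read a NIfTI (.nii/.nii.gz) or NRRD (.nrrd) volume as a canonical CTVolume."""
    p = str(path)
    low = p.lower()
    if low.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(p)
        data = np.asarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got {data.ndim}D in {p}")
        return _volume_from_lps_affine(data, _RAS_TO_LPS @ img.affine)
    if low.endswith(".nrrd"):
        from . import nrrdio

        return nrrdio.read_nrrd(p)
    ext = os.path.splitext(p)[1]
    raise ValueError(f"unsupported volume format {ext!r}; expected .nii, .nii.gz or .nrrd")


def resample_volume_rigid(
    vol: CTVolume, R, t, fill: float = -1000.0, order: int = 1
) -> CTVolume:
    """Resample ``vol`` after the rigid motion ``x -> R x + t`` of the patient.

    The output grid has identity orientation and the same spacing, covering
    the transformed bounding box; interpolation is linear by default.
    """
    from scipy import ndimage

    R = np.asarray(R, dtype=float)
    t = np.asarray(t, dtype=float)
    shape = np.array(vol.shape)
    corners_idx = np.array(
        [[i, j, k] for i in (0, shape[0] - 1) for j in (0, shape[1] - 1)
         for k in (0, shape[2] - 1)]
    )
    corners = vol.index_to_physical(corners_idx) @ R.T + t
    lo, hi = corners.min(axis=0), corners.max(axis=0)
    spacing = vol.spacing
    n = np.ceil((hi - lo) / spacing).astype(int) + 1
    # index_out -> physical_out -> physical_in -> index_in, all affine
    M_in = vol.orientation * spacing  # same spacing on both grids
    A = np.linalg.inv(M_in) @ R.T @ np.diag(spacing)
    offset = np.linalg.inv(M_in) @ (R.T @ (lo - t) - vol.origin)
    out = ndimage.affine_transform(
        vol.voxels.astype(np.float32), A, offset=offset, output_shape=tuple(n),
        order=order, mode="constant", cval=np.float32(fill),
    )
    return CTVolume(voxels=out, spacing=spacing, origin=lo, orientation=np.eye(3))


def write_volume(vol: CTVolume, path: str | os.PathLike) -> None:
    """Write a CTVolume to NIfTI or NRRD, preserving geometry."""
    p = str(path)
    low = p.lower()
    if low.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine_ras = _RAS_TO_LPS @ vol.affine
        nib.save(nib.Nifti1Image(np.asarray(vol.voxels), affine_ras), p)
        return
    if low.endswith(".nrrd"):
        from . import nrrdio

        nrrdio.write_nrrd(vol, p)
        return
    ext = os.path.splitext(p)[1]
    raise ValueError(f"unsupported volume format {ext!r}; expected .nii, .nii.gz or .nrrd")
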