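"""Bone isolation: HU thresholding plus seeded region growing / removal.

Seeds are physical points (mm); connectivity is 26-neighbour in 3D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import CTVolume

_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class BinaryMask:
    """Boolean voxel grid sharing the geometry of its source CTVolume."""

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    orientation: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)

    @property
    def shape(self):
        return self.voxels.shape

    @property
    def volume_mm3(self) -> float:
        return float(self.voxels.sum()) * float(np.prod(self.spacing))

    def _as_volume_geometry(self) -> CTVolume:
        return CTVolume(
            voxels=self.voxels.astype(np.uint8),
            spacing=self.spacing,
            origin=self.origin,
            orientation=self.orientation,
        )

    def physical_to_nearest_voxel(self, point) -> tuple[int, int, int]:
        return self._as_volume_geometry().physical_to_nearest_voxel(point)

    def save(self, path: str) -> None:
        from .volume_io import write_volume

        write_volume(self._as_volume_geometry(), path)


def threshold_mask(vol: CTVolume, hu_low: float = 200.0, hu_high: float = np.inf) -> BinaryMask:
    """Voxels with ``hu_low <= value <= hu_high`` (inclusive on both ends).

    The default 200 HU lower bound is a configurable stand-in for a per-case
    expert threshold choice.
    """
    if not hu_low < hu_high:
        raise ValueError(f"hu_low ({hu_low}) must be below hu_high ({hu_high})")
    mask = (vol.voxels >= hu_low) & (vol.voxels <= hu_high)
    return BinaryMask(mask, vol.spacing, vol.origin, vol.orientation)


def _seed_index(mask: BinaryMask, seed) -> tuple[int, int, int]:
    idx = mask.physical_to_nearest_voxel(seed)
    if not mask.voxels[idx]:
        true_idx = np.argwhere(mask.voxels)
        if true_idx.size == 0:
            raise ValueError("seed lies on a false voxel and the mask is empty")
        d2 = ((true_idx - np.array(idx)) ** 2).sum(axis=1)
        nearest = true_idx[int(np.argmin(d2))]
        raise ValueError(
            f"seed maps to a false voxel at index {idx}; "
            f"nearest true voxel is at index {tuple(int(v) for v in nearest)}"
        )
    return idx


def region_grow(mask: BinaryMask, seed) -> BinaryMask:
    """The 26-connected component of ``mask`` containing the physical ``seed``."""
    idx = _seed_index(mask, seed)
    labels, _ = ndimage.label(mask.voxels, structure=_STRUCTURE_26)
    keep = labels == labels[idx]
    return BinaryMask(keep, mask.spacing, mask.origin, mask.orientation)


def remove_component(mask: BinaryMask, seed) -> BinaryMask:
    """Delete the seed's 26-connected component; all other voxels unchanged."""
    idx = _seed_index(mask, seed)
    labels, _ = ndimage.label(mask.voxels, structure=_STRUCTURE_26)
    keep = mask.voxels & (labels != labels[idx])
    return BinaryMask(keep, mask.spacing, mask.origin, mask.orientation)
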