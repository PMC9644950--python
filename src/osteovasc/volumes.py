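"""Voxel-grid containers for cortical-bone volumes.

Arrays are indexed ``(z, y, x)`` with axis 0 the stack axis, which by
convention is the bone's long axis.  World coordinates are ``(x, y, z)`` in
micrometres with the origin at the volume corner; the centre of voxel
``(iz, iy, ix)`` sits at ``((ix + 0.5) h, (iy + 0.5) h, (iz + 0.5) h)`` for
voxel size ``h``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import DegenerateInputError  # noqa: F401  (re-export, historical home)


@dataclass
class GrayscaleVolume:
    """A 3D grey-value image with isotropic voxel size in micrometres."""

    voxels: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³."""
        return float(self.voxel_size) ** 3


@dataclass
class BinaryVolume:
    """A 3D boolean mask with isotropic voxel size and a role tag.

    ``label`` records what the mask represents in the segmentation pipeline:
    ``mineralised``, ``solid_cortex``, ``pores``, ``canals``, ``lacunae`` or
    ``exclusion``.
    """

    voxels: np.ndarray
    voxel_size: float
    label: str = field(default="mask")

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume(self) -> float:
        return float(self.voxel_size) ** 3

    def count(self) -> int:
        """Number of foreground voxels."""
        return int(self.voxels.sum())

    def volume_um3(self) -> float:
        """Total foreground volume in μm³ (voxel count × voxel volume)."""
        return self.count() * self.voxel_volume


def voxel_centers_um(shape: tuple[int, int, int], voxel_size: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """World coordinates (x, y, z in μm) of voxel centres, as broadcastable grids
    matching the ``(z, y, x)`` array layout."""
    nz, ny, nx = shape
    h = float(voxel_size)
    z = (np.arange(nz, dtype=np.float64) + 0.5)[:, None, None] * h
    y = (np.arange(ny, dtype=np.float64) + 0.5)[None, :, None] * h
    x = (np.arange(nx, dtype=np.float64) + 0.5)[None, None, :] * h
    return x, y, z


def write_tiff(path, volume: GrayscaleVolume | BinaryVolume) -> None:
    """Write a volume as a multi-page TIFF (binary masks as 8-bit 0/255)."""
    arr = volume.voxels
    if arr.dtype == bool:
        arr = (arr.astype(np.uint8)) * 255
    tifffile.imwrite(
        str(path),
        arr,
        resolution=(1e4 / volume.voxel_size, 1e4 / volume.voxel_size),
    )


def read_grayscale_tiff(path, voxel_size: float) -> GrayscaleVolume:
    return GrayscaleVolume(tifffile.imread(str(path)), voxel_size)


def read_mask_tiff(path, voxel_size: float, label: str = "mask") -> BinaryVolume:
    return BinaryVolume(tifffile.imread(str(path)) > 0, voxel_size, label)
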