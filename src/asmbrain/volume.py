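"""3D image volume container with physical voxel spacing.

Axis convention used throughout the package (volume index axes -> anatomy):

* axis 0 (``x``): left-right.  Positive ``x`` is the left hemisphere
  (*sinister*), negative ``x`` the right (*dexter*).  Sagittal slices are
  planes of constant ``x``.
* axis 1 (``y``): posterior-anterior.  Positive ``y`` is anterior (frontal).
* axis 2 (``z``): inferior-superior.  Positive ``z`` is superior.

World coordinates are millimetres with the origin at the volume centre, so a
voxel index ``i`` along an axis with ``n`` voxels and spacing ``s`` sits at
``(i - (n - 1) / 2) * s`` mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np


@dataclass
class Volume:
    """A 3D scalar grid plus per-axis voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        """World (mm) coordinates of voxel centres along ``axis``."""
        n = self.data.shape[axis]
        return (np.arange(n) - (n - 1) / 2.0) * self.spacing[axis]

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Convert (N, 3) mm coordinates to fractional voxel indices."""
        points_mm = np.atleast_2d(np.asarray(points_mm, dtype=np.float64))
        centre = (np.asarray(self.shape) - 1) / 2.0
        return points_mm / np.asarray(self.spacing) + centre

    def voxel_to_world(self, index: np.ndarray) -> np.ndarray:
        """Convert (N, 3) voxel indices to mm coordinates."""
        index = np.atleast_2d(np.asarray(index, dtype=np.float64))
        centre = (np.asarray(self.shape) - 1) / 2.0
        return (index - centre) * np.asarray(self.spacing)

    def sample(self, points_mm: np.ndarray, order: int = 1, cval: float = 0.0) -> np.ndarray:
        """Trilinear (order=1) interpolation of the volume at mm coordinates."""
        from scipy.ndimage import map_coordinates

        vox = self.world_to_voxel(points_mm)
        return map_coordinates(self.data, vox.T, order=order, mode="constant", cval=cval)

    def robust_max(self, percentile: float = 99.5) -> float:
        """High percentile of the intensity distribution, noise-tolerant maximum."""
        return float(np.percentile(self.data, percentile))

    def copy_with(self, data: np.ndarray) -> "Volume":
        return Volume(np.asarray(data, dtype=np.float64), self.spacing)

    # ------------------------------------------------------------------ I/O
    def to_nifti(self, path: str) -> None:
        affine = np.diag(list(self.spacing) + [1.0])
        # place the world origin at the volume centre
        affine[:3, 3] = -((np.asarray(self.shape) - 1) / 2.0) * np.asarray(self.spacing)
        img = nib.Nifti1Image(self.data.astype(np.float32), affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, path)

    @classmethod
    def from_nifti(cls, path: str) -> "Volume":
        img = nib.load(path)
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(data, spacing)
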