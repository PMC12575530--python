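"""Voxel-grid container with physical spacing, plus NIfTI I/O.

Volumes are stored in array index order (i, j, k) with per-axis spacing in
millimetres.  World coordinates are ``index * spacing`` — the generator and
all geometry code work in this axis-aligned RAS-like frame, which is what an
affine of ``diag(spacing)`` encodes in the NIfTI header.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume"]


@dataclass
class ImageVolume:
    """A 3-D scalar or binary volume with physical voxel spacing (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical size of the grid along each axis."""
        return np.asarray(self.shape) * np.asarray(self.spacing)

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_mm(self, idx: np.ndarray) -> np.ndarray:
        """Map (fractional) voxel indices to world mm coordinates."""
        return np.asarray(idx, dtype=float) * np.asarray(self.spacing)

    def mm_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm coordinates to fractional voxel indices."""
        return np.asarray(xyz, dtype=float) / np.asarray(self.spacing)

    def same_grid(self, other: "ImageVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)

    # --- NIfTI round trip -------------------------------------------------

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(list(self.spacing) + [1.0])
        data = self.data
        if data.dtype == bool:
            data = data.astype(np.uint8)
        return nib.Nifti1Image(data, affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "ImageVolume":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asanyarray(img.dataobj), spacing)
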