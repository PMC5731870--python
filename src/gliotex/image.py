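"""Core imaging containers: 3D scalar volumes and boolean region masks.

A :class:`VolumeImage` is a 3D scalar field on a regular grid with known
physical voxel spacing (mm) and a modality tag; a :class:`ROIMask` is a
boolean field on the same grid marking a region of interest (tumor or
normal-appearing white matter).  Axis order is (x, y, z) with 0-based
indices; the third axis is the slice (axial) direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Tuple

import nibabel as nib
import numpy as np

Modality = Literal["t1post", "flair"]
MaskRole = Literal["tumor", "nawm"]

MODALITIES: Tuple[str, str] = ("t1post", "flair")


@dataclass
class VolumeImage:
    """3D scalar image with physical voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel intensities; must be finite.
    spacing_mm : tuple of 3 floats
        Physical voxel size along each axis, mm; strictly positive.
    modality : str
        Acquisition tag, ``"t1post"`` or ``"flair"``.
    """

    values: np.ndarray
    spacing_mm: Tuple[float, float, float]
    modality: str = "t1post"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def to_nifti(self, path: str | Path) -> None:
        """Write as NIfTI with a diagonal affine encoding the spacing."""
        affine = np.diag(list(self.spacing_mm) + [1.0])
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, modality: str = "t1post") -> "VolumeImage":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float64)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(values=data, spacing_mm=spacing, modality=modality)


@dataclass
class ROIMask:
    """Boolean 3D mask aligned to a :class:`VolumeImage` grid."""

    values: np.ndarray
    spacing_mm: Tuple[float, float, float]
    role: str = "tumor"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={self.values.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * float(np.prod(self.spacing_mm))

    def is_empty(self) -> bool:
        return not bool(self.values.any())

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag(list(self.spacing_mm) + [1.0])
        nib.save(nib.Nifti1Image(self.values.astype(np.uint8), affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, role: str = "tumor") -> "ROIMask":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj) > 0
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(values=data, spacing_mm=spacing, role=role)


@dataclass
class QuantizedROI:
    """Integer gray levels 1..G at in-mask voxels (0 elsewhere).

    Input container for all texture-matrix computations.  ``levels`` is a
    full-grid int array: every voxel inside ``mask`` holds a level in
    [1, G], every voxel outside holds 0.
    """

    levels: np.ndarray
    mask: ROIMask
    n_levels: int
    spacing_mm: Tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        if self.levels.shape != self.mask.shape:
            raise ValueError("levels grid and mask shape differ")
        if self.n_levels < 2:
            raise ValueError(f"G must be >= 2, got {self.n_levels}")
        inside = self.levels[self.mask.values]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_levels):
            raise ValueError("in-mask levels must lie in [1, G]")

    @property
    def in_mask_levels(self) -> np.ndarray:
        return self.levels[self.mask.values]

    @property
    def n_voxels(self) -> int:
        return self.mask.n_voxels
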