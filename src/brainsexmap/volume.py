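"""3D volume and atlas containers with NIfTI-1 I/O.

A :class:`Volume` is the unit every pipeline stage transforms: a 3D intensity
grid with voxel spacing in mm. An :class:`Atlas` is an integer parcellation on
the same grid (label 0 = background). Both round-trip through NIfTI-1 via
nibabel with a diagonal affine built from the voxel spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

from .errors import ShapeError

__all__ = ["Volume", "Atlas"]


@dataclass
class Volume:
    data: np.ndarray                       # (D, H, W) float32
    voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ShapeError(f"expected a 3D grid, got shape {self.data.shape}")
        if any(v <= 0 for v in self.voxel_mm):
            raise ValueError(f"voxel dimensions must be positive, got {self.voxel_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_mm))

    def copy(self) -> "Volume":
        return replace(self, data=self.data.copy())

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_mm) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self, path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine())
        img.header.set_zooms(self.voxel_mm)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path) -> "Volume":
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float32)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return cls(data=data, voxel_mm=zooms, origin=origin)


@dataclass
class Atlas:
    """Labeled parcellation sharing the template grid; label 0 is background."""

    labels: np.ndarray                     # (D, H, W) int16
    names: dict[int, str] = field(default_factory=dict)
    voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int16)
        present = self.region_ids
        missing = [int(r) for r in present if int(r) not in self.names]
        if missing:
            raise ValueError(f"regions without a name: {missing}")

    @property
    def region_ids(self) -> list[int]:
        return [int(r) for r in np.unique(self.labels) if r != 0]

    def region_mask(self, region_id: int) -> np.ndarray:
        return self.labels == region_id

    def to_nifti(self, path) -> None:
        aff = np.diag(list(self.voxel_mm) + [1.0])
        img = nib.Nifti1Image(self.labels.astype(np.int16), aff)
        img.header.set_zooms(self.voxel_mm)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path, names: dict[int, str] | None = None) -> "Atlas":
        img = nib.load(str(path))
        labels = np.asarray(img.get_fdata()).astype(np.int16)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        if names is None:
            names = {int(r): f"region_{int(r):02d}" for r in np.unique(labels) if r != 0}
        return cls(labels=labels, names=names, voxel_mm=zooms)
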