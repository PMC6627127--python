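"""Shared image carriers: scalar volumes, ROI masks and multi-b DWI series.

All volumes are plain 3D numpy arrays with an explicit voxel spacing in mm.
NIfTI-1 is the on-disk format (via nibabel); spacing is carried in the
affine diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "RoiMask",
    "DWISeries",
    "GeometryError",
    "B_VALUES_FULL",
    "B_VALUES_REDUCED",
]

#: Full diffusion-weighting schedule in s/mm^2 (12 b-values).
B_VALUES_FULL: tuple[int, ...] = (0, 10, 20, 30, 50, 80, 100, 200, 400, 800, 1000, 2000)

#: Reduced schedule used for ADC / SEM / DKI, which target tissue diffusion
#: and therefore skip the perfusion-sensitive low-b range.
B_VALUES_REDUCED: tuple[int, ...] = (0, 200, 400, 800, 1000, 2000)


class GeometryError(ValueError):
    """Raised when two volumes that must share a grid do not."""


@dataclass
class ImageVolume:
    """A 3D scalar grid with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"invalid spacing {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_geometry(self, other: "ImageVolume | RoiMask") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)

    def require_geometry(self, other: "ImageVolume | RoiMask") -> None:
        if not self.same_geometry(other):
            raise GeometryError(
                f"geometry mismatch: {self.shape}@{self.spacing} vs "
                f"{other.shape}@{other.spacing}"
            )

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag([*self.spacing, 1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.float64), affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "ImageVolume":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj, dtype=float), spacing)


@dataclass
class RoiMask:
    """Binary 3D ROI aligned to a reference grid.

    ``necrosis`` optionally flags voxels inside the ROI that belong to a
    necrotic or cystic region; such voxels are excluded from every ROI
    statistic (they stay part of the anatomical outline but never of the
    signal sample).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    necrosis: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"invalid spacing {self.spacing}")
        if self.necrosis is not None:
            self.necrosis = np.asarray(self.necrosis).astype(bool)
            if self.necrosis.shape != self.data.shape:
                raise GeometryError("necrosis flag grid does not match the mask grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def active(self) -> np.ndarray:
        """Boolean grid of voxels that enter ROI statistics."""
        if self.necrosis is None:
            return self.data
        return self.data & ~self.necrosis

    def count(self) -> int:
        return int(self.data.sum())

    def same_geometry(self, other: "ImageVolume | RoiMask") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag([*self.spacing, 1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, necrosis_path: str | Path | None = None) -> "RoiMask":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        necrosis = None
        if necrosis_path is not None:
            necrosis = np.asarray(nib.load(str(necrosis_path)).dataobj) > 0
        return cls(np.asarray(img.dataobj) > 0, spacing, necrosis=necrosis)


@dataclass
class DWISeries:
    """An ordered multi-b-value DWI acquisition: one volume per b-value."""

    b_values: tuple[float, ...]
    volumes: list[ImageVolume]

    def __post_init__(self) -> None:
        self.b_values = tuple(float(b) for b in self.b_values)
        if len(self.b_values) != len(self.volumes):
            raise ValueError("one volume per b-value required")
        if any(b < 0 for b in self.b_values):
            raise ValueError("b-values must be non-negative")
        if any(b2 <= b1 for b1, b2 in zip(self.b_values, self.b_values[1:])):
            raise ValueError("b-values must be strictly increasing")
        ref = self.volumes[0]
        for v in self.volumes[1:]:
            ref.require_geometry(v)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.volumes[0].spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes[0].shape

    def roi_mean_signal(self, mask: RoiMask) -> np.ndarray:
        """ROI-mean signal per b-value over the active (non-necrotic) voxels."""
        self.volumes[0].require_geometry(mask)
        sel = mask.active
        if not sel.any():
            raise ValueError("empty ROI")
        return np.array([v.data[sel].mean() for v in self.volumes])

    def subset(self, b_subset: tuple[float, ...]) -> "DWISeries":
        """Restrict the series to a sub-schedule (must be present exactly)."""
        index = {b: i for i, b in enumerate(self.b_values)}
        missing = [b for b in b_subset if b not in index]
        if missing:
            raise ValueError(f"b-values {missing} not acquired")
        return DWISeries(tuple(b_subset), [self.volumes[index[b]] for b in b_subset])
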