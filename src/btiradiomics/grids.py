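"""Voxel-grid containers and NIfTI round-tripping.

A :class:`VoxelGrid` is a 3D scalar image with physical spacing (mm); a
:class:`MaskVolume` is a binary volume aligned to a grid.  All physical
quantities in this package are millimetres and millilitres, voxel indices
are 0-based, and arrays are indexed ``(i, j, k)`` with per-axis spacing
``spacing_mm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VoxelGrid", "MaskVolume", "load_volume", "save_volume", "load_mask", "save_mask"]


@dataclass
class VoxelGrid:
    """A 3D intensity image with physical geometry.

    Parameters
    ----------
    intensities : (ni, nj, nk) float array
    spacing_mm : per-axis voxel spacing, strictly positive
    origin_mm : physical coordinate of voxel (0, 0, 0)
    axcodes : orientation code triple, e.g. ``("R", "A", "S")``
    """

    intensities: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axcodes: tuple[str, str, str] = ("R", "A", "S")

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        valid = {"R", "L", "A", "P", "S", "I"}
        if len(self.axcodes) != 3 or any(c not in valid for c in self.axcodes):
            raise ValueError(f"invalid orientation codes {self.axcodes}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def copy_with(self, intensities: np.ndarray) -> "VoxelGrid":
        if intensities.shape != self.shape:
            raise ValueError("shape mismatch")
        return VoxelGrid(intensities, self.spacing_mm, self.origin_mm, self.axcodes)


@dataclass
class MaskVolume:
    """A binary volume aligned to a :class:`VoxelGrid`."""

    data: np.ndarray
    grid: VoxelGrid = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.data.shape} does not match grid {self.grid.shape}"
            )
        if self.data.dtype != bool:
            vals = np.unique(self.data)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("mask values must be in {0, 1}")
            self.data = self.data.astype(bool)

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_ml(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_mm3 / 1000.0

    def same_grid_as(self, other: "MaskVolume") -> bool:
        return (
            self.grid.shape == other.grid.shape
            and self.grid.spacing_mm == other.grid.spacing_mm
        )


def _affine(spacing: tuple[float, float, float], origin: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_volume(grid: VoxelGrid, path: str) -> None:
    img = nib.Nifti1Image(np.asarray(grid.intensities, dtype=np.float32),
                          _affine(grid.spacing_mm, grid.origin_mm))
    nib.save(img, path)


def load_volume(path: str) -> VoxelGrid:
    img = nib.load(path)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return VoxelGrid(np.asanyarray(img.dataobj).astype(np.float64), spacing, origin)


def save_mask(mask: MaskVolume, path: str) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8),
                          _affine(mask.grid.spacing_mm, mask.grid.origin_mm))
    nib.save(img, path)


def load_mask(path: str, grid: VoxelGrid | None = None) -> MaskVolume:
    vol = load_volume(path)
    if grid is None:
        grid = vol
    return MaskVolume(vol.intensities > 0.5, grid)
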