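"""Volumetric map and ROI handling.

The package works on proton-density fat-fraction (PDFF) maps: 3D scalar
volumes on the percent scale (0-100 %), with anisotropic physical voxel
spacing in mm, paired with binary region-of-interest masks for individual
muscles.  Volumes and masks travel as NIfTI files; in memory they are plain
dataclasses wrapping numpy arrays.

No reorientation is performed: masks must be drawn on the same grid as the
map they segment, and voxel indices are 0-based throughout.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

from .exceptions import (
    DomainError,
    EmptyRoiError,
    GridAlignmentError,
    VolumeFormatError,
)

__all__ = [
    "VolumeGrid",
    "RoiMask",
    "RoiSample",
    "read_volume",
    "write_volume",
    "read_mask",
    "compute_pdff",
    "extract_roi",
    "MUSCLES",
    "SIDES",
    "DEFAULT_LABEL_MAP",
]

MUSCLES = ("ES", "PS")
SIDES = ("right", "left")

#: Convention for single-file labeled masks: label -> (muscle, side).
DEFAULT_LABEL_MAP = {1: ("ES", "right"), 2: ("ES", "left"),
                     3: ("PS", "right"), 4: ("PS", "left")}


@dataclass
class VolumeGrid:
    """A 3D scalar grid with physical voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values; PDFF maps use the percent scale.
    spacing : tuple of float
        Physical voxel edge lengths (sx, sy, sz) in mm, all > 0.
    origin : tuple of float
        Physical position of voxel (0, 0, 0) in mm.
    meta : dict
        Free-form provenance (e.g. degenerate-voxel tallies).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3D volume, got {self.values.ndim} dimensions")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(
                f"spacing must be three positive lengths, got {self.spacing}")
        self.origin = tuple(float(x) for x in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of a single voxel in mm^3."""
        sx, sy, sz = self.spacing
        return sx * sy * sz


@dataclass
class RoiMask:
    """Binary mask aligned to a :class:`VolumeGrid`, labeled by muscle and side."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    muscle: str = "ES"
    side: str = "right"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3D mask, got {self.values.ndim} dimensions")
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.muscle not in MUSCLES:
            raise DomainError(f"muscle must be one of {MUSCLES}, got {self.muscle!r}")
        if self.side not in SIDES + ("bilateral",):
            raise DomainError(f"side must be right/left, got {self.side!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())


@dataclass(frozen=True)
class RoiSample:
    """The PDFF values inside one mask, with the ROI's physical volume."""

    voxel_values: np.ndarray
    voxel_count: int
    physical_volume: float  # mm^3

    def __post_init__(self) -> None:
        if self.voxel_count != len(self.voxel_values):
            raise DomainError("voxel_count must equal len(voxel_values)")
        if self.physical_volume <= 0:
            raise DomainError("physical_volume must be positive")


def _check_aligned(a, b, what: str = "grids") -> None:
    if a.shape != b.shape:
        raise GridAlignmentError(
            f"{what} differ in shape: {a.shape} vs {b.shape}")
    if not np.array_equal(a.spacing, b.spacing):
        raise GridAlignmentError(
            f"{what} differ in spacing: {a.spacing} vs {b.spacing}")


def read_volume(path: os.PathLike | str) -> VolumeGrid:
    """Read a 3D NIfTI volume into a :class:`VolumeGrid`.

    Spacing comes from the header zooms and the origin from the affine
    translation.  Raises :class:`VolumeFormatError` for missing files,
    non-3D images, or non-positive spacing.
    """
    if not os.path.exists(path):
        raise VolumeFormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise VolumeFormatError(f"could not read {path}: {exc}") from exc
    if img.ndim != 3:
        raise VolumeFormatError(
            f"{path}: expected 3 spatial dimensions, got shape {img.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise VolumeFormatError(f"{path}: non-positive voxel spacing {zooms}")
    origin = tuple(float(x) for x in img.affine[:3, 3])
    values = np.asarray(img.dataobj, dtype=np.float64)
    return VolumeGrid(values=values, spacing=zooms, origin=origin)


def write_volume(path: os.PathLike | str, grid: VolumeGrid) -> None:
    """Write a :class:`VolumeGrid` as NIfTI (.nii or .nii.gz)."""
    affine = np.diag(list(grid.spacing) + [1.0])
    affine[:3, 3] = grid.origin
    img = nib.Nifti1Image(grid.values, affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def read_mask(path: os.PathLike | str, muscle: str, side: str,
              label: int | None = None) -> RoiMask:
    """Read a mask NIfTI; ``label`` selects one label of a labeled file,
    otherwise any nonzero voxel is foreground."""
    grid = read_volume(path)
    vals = np.rint(grid.values).astype(int)
    fg = (vals == label) if label is not None else (vals != 0)
    return RoiMask(values=fg, spacing=grid.spacing, muscle=muscle, side=side)


def compute_pdff(fat: VolumeGrid, water: VolumeGrid) -> VolumeGrid:
    """Proton-density fat fraction from fat/water signal magnitudes.

    PDFF is the fat signal over the sum of fat and water signals, on the
    percent scale: ``100 * F / (F + W)``.  Voxels where both signals are
    zero (background air) are defined as 0 % and tallied in
    ``meta["degenerate_voxels"]`` rather than raising — masks should
    exclude them, and the tally exposes mask leakage.
    """
    _check_aligned(fat, water, "fat/water volumes")
    f, w = fat.values, water.values
    if (f < 0).any() or (w < 0).any():
        raise DomainError("signal magnitudes must be non-negative")
    denom = f + w
    zero = denom == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        pdff = np.where(zero, 0.0, 100.0 * f / np.where(zero, 1.0, denom))
    return VolumeGrid(values=pdff, spacing=fat.spacing, origin=fat.origin,
                      meta={"degenerate_voxels": int(zero.sum())})


def extract_roi(volume: VolumeGrid, mask: RoiMask) -> RoiSample:
    """Collect the in-mask voxel values and the ROI's physical volume."""
    _check_aligned(volume, mask, "volume and mask")
    fg = mask.values
    n = int(fg.sum())
    if n == 0:
        raise EmptyRoiError(f"mask {mask.muscle}/{mask.side} has no foreground voxel")
    return RoiSample(voxel_values=volume.values[fg],
                     voxel_count=n,
                     physical_volume=n * volume.voxel_volume)


def crop_to_mask(volume: VolumeGrid, mask: RoiMask, margin: int = 1
                 ) -> tuple[VolumeGrid, RoiMask]:
    """Crop both grids to the mask bounding box plus ``margin`` voxels.

    Texture features depend only on in-mask voxels, so cropping before
    resampling changes nothing downstream while keeping grids small.
    """
    _check_aligned(volume, mask)
    fg = mask.values
    if not fg.any():
        raise EmptyRoiError("cannot crop to an empty mask")
    sl = []
    for ax in range(3):
        proj = fg.any(axis=tuple(i for i in range(3) if i != ax))
        idx = np.nonzero(proj)[0]
        lo = max(int(idx[0]) - margin, 0)
        hi = min(int(idx[-1]) + margin + 1, fg.shape[ax])
        sl.append(slice(lo, hi))
    sl = tuple(sl)
    new_origin = tuple(volume.origin[i] + sl[i].start * volume.spacing[i]
                       for i in range(3))
    vol = VolumeGrid(values=volume.values[sl], spacing=volume.spacing,
                     origin=new_origin)
    msk = replace(mask, values=mask.values[sl])
    return vol, msk
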