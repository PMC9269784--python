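"""Reading, validating and writing binary 3D region-of-interest masks.

Masks are kept in the file's own voxel lattice: no resampling and no
reorientation to anatomical axes is performed, because the downstream
bounding box is axis-aligned in image space and any resampling would
change it. The z extent of a voxel is the inter-slice spacing (the lattice
step), not the slice thickness, which is an acquisition property.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import (
    DimensionalityError,
    EmptyROIError,
    MaskFormatError,
    MetadataError,
)

logger = logging.getLogger(__name__)

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_NRRD_SUFFIXES = (".nrrd", ".nhdr")


@dataclass
class VoxelMask:
    """A binary 3D occupancy grid with physical voxel spacing.

    Attributes
    ----------
    grid:
        uint8 array of 0/1 values, axis order (x, y, z).
    spacing:
        Physical size of one voxel along each axis, in mm; strictly positive.
    origin:
        Physical coordinate of the first voxel (mm). Informational only.
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 3:
            raise DimensionalityError(
                f"mask grid must be 3D, got {grid.ndim}D"
            )
        self.grid = (grid != 0).astype(np.uint8)
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(
            not np.isfinite(s) or s <= 0 for s in spacing
        ):
            raise MetadataError(f"invalid voxel spacing {self.spacing!r}")
        self.spacing = spacing
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def voxel_count(self) -> int:
        """Number of foreground voxels."""
        return int(self.grid.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        """Physical volume of a single voxel in mm^3."""
        sx, sy, sz = self.spacing
        return sx * sy * sz


def _detect_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    name = path.name.lower()
    if name.endswith(_NIFTI_SUFFIXES):
        return "nifti"
    if name.endswith(_NRRD_SUFFIXES):
        return "nrrd"
    raise MaskFormatError(f"cannot infer mask format from {path.name!r}")


def read_mask(path: str | Path, format: str = "auto") -> VoxelMask:
    """Read a binary ROI mask from a NIfTI or NRRD file.

    Nonzero voxels are binarised to 1. The grid axis order is normalised
    to (x, y, z); spacing is taken from the file header.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"nifti"``, ``"nrrd"`` or ``"auto"`` (infer from suffix).
    """
    path = Path(path)
    if not path.exists():
        raise MaskFormatError(f"no such file: {path}")
    fmt = _detect_format(path, format)
    if fmt == "nifti":
        return _read_nifti(path)
    if fmt == "nrrd":
        return _read_nrrd(path)
    raise MaskFormatError(f"unknown format {fmt!r}")


def _read_nifti(path: Path) -> VoxelMask:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise MaskFormatError(f"could not read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[3] == 1 else data
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path.name}: expected a 3D scalar volume, got shape {data.shape}"
        )
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise MetadataError(f"{path.name}: missing or zero voxel spacing {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    # nibabel data axes are already (i, j, k) = (x, y, z) in the file lattice
    return VoxelMask(grid=data, spacing=tuple(float(z) for z in zooms), origin=origin)


def _read_nrrd(path: Path) -> VoxelMask:
    import SimpleITK as sitk

    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:
        raise MaskFormatError(f"could not read {path} as NRRD: {exc}") from exc
    if img.GetDimension() != 3:
        raise DimensionalityError(
            f"{path.name}: expected a 3D scalar volume, got {img.GetDimension()}D"
        )
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    spacing = img.GetSpacing()  # (sx, sy, sz)
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise MetadataError(f"{path.name}: missing or zero voxel spacing {spacing}")
    return VoxelMask(
        grid=arr.transpose(2, 1, 0),
        spacing=tuple(float(s) for s in spacing),
        origin=tuple(float(v) for v in img.GetOrigin()),
    )


def write_mask(mask: VoxelMask, path: str | Path, format: str = "auto") -> None:
    """Write a mask so that :func:`read_mask` recovers grid and spacing exactly."""
    path = Path(path)
    fmt = _detect_format(path, format)
    try:
        if fmt == "nifti":
            _write_nifti(mask, path)
        elif fmt == "nrrd":
            _write_nrrd(mask, path)
        else:
            raise MaskFormatError(f"unknown format {fmt!r}")
    except OSError as exc:
        raise OSError(f"cannot write mask to {path}: {exc}") from exc


def _write_nifti(mask: VoxelMask, path: Path) -> None:
    import nibabel as nib

    affine = np.diag(list(mask.spacing) + [1.0])
    affine[:3, 3] = mask.origin
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def _write_nrrd(mask: VoxelMask, path: Path) -> None:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(mask.grid.transpose(2, 1, 0))
    img.SetSpacing(mask.spacing)
    img.SetOrigin(mask.origin)
    sitk.WriteImage(img, str(path))


def validate_mask(
    mask: VoxelMask, require_single_component: bool = False
) -> VoxelMask:
    """Check a mask is usable as a lesion ROI.

    Raises :class:`EmptyROIError` on an all-zero mask. With
    ``require_single_component`` the largest 26-connected foreground
    component is retained and the number of discarded components logged;
    the default keeps the ROI exactly as delineated.
    """
    if mask.voxel_count == 0:
        raise EmptyROIError("mask has no foreground voxels")
    if not require_single_component:
        return mask
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labels, n = ndimage.label(mask.grid, structure=structure)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask.grid, labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    logger.info("validate_mask: removed %d of %d connected components", n - 1, n)
    return VoxelMask(
        grid=(labels == keep).astype(np.uint8),
        spacing=mask.spacing,
        origin=mask.origin,
    )
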