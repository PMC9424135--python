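"""Volume and mask containers with NIfTI I/O.

All volumes are reoriented on load to the canonical RAS+ axis order
(left->right, posterior->anterior, inferior->superior).  The "axial" and
"coronal" view axes used throughout the package are defined against this
canonical order: axial slices stack along the third (inferior-superior)
axis, coronal slices along the second (posterior-anterior) axis.  The
left-right axis is the first axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "BinaryMask",
    "SubjectRecord",
    "read_volume",
    "write_mask",
    "binarize",
    "split_by_hemisphere",
    "LR_AXIS",
    "VIEW_AXES",
]

#: index of the left-right axis in canonical (RAS+) voxel order
LR_AXIS = 0
#: stacking axis for each 2D view, in canonical voxel order
VIEW_AXES = {"axial": 2, "coronal": 1}


class DimensionalityError(ValueError):
    """Image is not a 3D scalar volume."""


class CompatibilityError(ValueError):
    """Two grids that must match do not."""


@dataclass
class Volume:
    """A 3D scalar intensity grid with voxel spacing and orientation.

    Parameters
    ----------
    data
        3D array of intensities (arbitrary units).
    spacing
        Voxel size ``(sx, sy, sz)`` in millimetres, all positive.
    affine
        4x4 grid-to-world map.  Defaults to a diagonal map built from
        ``spacing``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D volume, got {self.data.ndim} axes"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class BinaryMask:
    """A {0,1} grid aligned to a reference :class:`Volume`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D mask, got {arr.ndim} axes"
            )
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be in {0, 1}")
        self.data = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def volume_voxels(self) -> int:
        """Foreground voxel count (|M| in the overlap metrics)."""
        return int(self.data.sum())


@dataclass
class SubjectRecord:
    """One subject: id, optional scan age, volume and optional mask."""

    id: str
    volume: Volume
    mask: Optional[BinaryMask] = None
    scan_age_weeks: Optional[float] = None
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mask is not None and self.mask.shape != self.volume.shape:
            raise CompatibilityError(
                f"mask shape {self.mask.shape} != volume shape {self.volume.shape}"
            )


def _canonical(img: nib.Nifti1Image) -> nib.Nifti1Image:
    return nib.as_closest_canonical(img)


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI-1 volume, reoriented to canonical RAS+ order.

    Raises
    ------
    DimensionalityError
        If the image is not 3D (a trailing singleton 4th axis is squeezed).
    """
    img = nib.load(str(path))
    img = _canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path}: expected a 3D image, got shape {data.shape}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data=np.asarray(data, dtype=np.float64), spacing=spacing,
                  affine=np.asarray(img.affine))


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a float volume as NIfTI-1 (.nii or .nii.gz)."""
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def write_mask(mask: BinaryMask, ref: Volume, path: str | Path) -> None:
    """Write a binary mask as unsigned 8-bit NIfTI with ``ref``'s geometry."""
    if mask.shape != ref.shape:
        raise CompatibilityError(
            f"mask shape {mask.shape} does not match reference {ref.shape}"
        )
    img = nib.Nifti1Image(mask.data.astype(np.uint8), ref.affine)
    img.header.set_zooms(ref.spacing)
    nib.save(img, str(path))


def binarize(vol: Volume, threshold: float) -> BinaryMask:
    """Threshold a (probability) volume: voxel -> 1 iff intensity > threshold."""
    return BinaryMask(data=(np.asarray(vol.data) > threshold).astype(np.uint8),
                      spacing=vol.spacing, affine=vol.affine)


def split_by_hemisphere(mask: BinaryMask, midline_index: Optional[int] = None
                        ) -> tuple[BinaryMask, BinaryMask]:
    """Split a mask at the left-right axis into (below-midline, rest).

    Voxels with index < ``midline_index`` along the left-right axis go to
    the first output.  The two outputs partition the input: their union is
    the input and their intersection is empty.  ``midline_index`` defaults
    to the middle index of the left-right axis.
    """
    n = mask.shape[LR_AXIS]
    if midline_index is None:
        midline_index = n // 2
    if not 0 <= midline_index < n:
        raise ValueError(f"midline index {midline_index} outside [0, {n})")
    low = np.zeros_like(mask.data)
    high = np.zeros_like(mask.data)
    sel_low = [slice(None)] * 3
    sel_low[LR_AXIS] = slice(0, midline_index)
    sel_high = [slice(None)] * 3
    sel_high[LR_AXIS] = slice(midline_index, None)
    low[tuple(sel_low)] = mask.data[tuple(sel_low)]
    high[tuple(sel_high)] = mask.data[tuple(sel_high)]
    mk = lambda d: BinaryMask(data=d, spacing=mask.spacing, affine=mask.affine)
    return mk(low), mk(high)
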