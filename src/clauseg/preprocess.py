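"""Preprocessing of brain-extracted volumes and its exact inverse.

Three steps are applied before slices reach a network: (1) z-score
normalisation over brain (nonzero) voxels, (2) centre-cropping every slice
to a uniform in-plane size (default 200 x 200), and (3) removal of the
first and last 25% of slices along the view's stacking axis.  Steps (2)
and (3) are inverted after prediction: the crop is padded back to the
original in-plane size and the trimmed slice range is filled with zeros.

A :class:`SliceStack` carries full provenance (view, retained slice range,
crop offsets, original shape) so that :func:`restore_volume` is an exact
inverse on the retained, uncropped region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .volume import Volume, VIEW_AXES

__all__ = ["PreprocSpec", "SliceStack", "zscore_normalize", "extract_slices",
           "restore_volume"]


class DegenerateInputError(ValueError):
    """Input has no usable intensity statistics."""


class ProvenanceError(ValueError):
    """SliceStack provenance is internally inconsistent."""


@dataclass(frozen=True)
class PreprocSpec:
    """Crop size, slice-trim fraction and normalisation mode.

    ``trim_fraction`` f removes the first and last ``floor(f * n)`` slices
    of an n-slice view; with the default 0.25 a 192-slice scan keeps the
    central 96 slices [48, 144).
    """

    crop_size: tuple[int, int] = (200, 200)
    trim_fraction: float = 0.25
    normalization: str = "zscore_nonzero"

    def __post_init__(self) -> None:
        if len(self.crop_size) != 2 or any(int(c) <= 0 for c in self.crop_size):
            raise ValueError(f"crop_size must be two positive ints, got {self.crop_size}")
        if not 0.0 <= self.trim_fraction < 0.5:
            raise ValueError(f"trim_fraction must lie in [0, 0.5), got {self.trim_fraction}")
        if self.normalization != "zscore_nonzero":
            raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclass
class SliceStack:
    """Ordered 2D slices from one view with inversion provenance.

    ``crop_offsets`` holds, per in-plane axis, the signed offset of the
    crop window: positive values mean the window started inside the
    original slice (cropping), negative values mean symmetric zero padding
    was added (original smaller than the crop size).
    """

    slices: np.ndarray                      # (n_slices, H, W)
    view: str
    retained_range: tuple[int, int]         # [first, last) along stack axis
    crop_offsets: tuple[int, int]
    original_shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        if self.view not in VIEW_AXES:
            raise ValueError(f"unknown view {self.view!r}")
        first, last = self.retained_range
        if self.slices.ndim != 3 or self.slices.shape[0] != last - first:
            raise ProvenanceError(
                f"slice count {self.slices.shape[0]} != retained range length {last - first}"
            )

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]


def zscore_normalize(vol: Volume) -> Volume:
    """Standardise brain (nonzero) voxels to zero mean, unit variance.

    Background voxels (exact zeros, as produced by brain extraction) are
    left at zero; statistics use the population standard deviation.
    """
    data = np.asarray(vol.data, dtype=np.float64)
    brain = data != 0
    if not brain.any():
        raise DegenerateInputError("volume has no nonzero voxels to normalise")
    vals = data[brain]
    mu = vals.mean()
    sigma = vals.std()
    if sigma == 0:
        raise DegenerateInputError("nonzero voxels have zero variance")
    out = np.zeros_like(data)
    out[brain] = (vals - mu) / sigma
    return Volume(data=out, spacing=vol.spacing, affine=vol.affine)


def _crop_pad_1d(n: int, c: int) -> tuple[int, slice, slice]:
    """Offset and source/destination slices mapping extent n onto extent c.

    Positive offset crops; negative pads.  Odd remainders give the extra
    pixel to the high-index side of whichever operation applies.
    """
    off = (n - c) // 2 if n >= c else -((c - n) // 2)
    if n >= c:
        return off, slice(off, off + c), slice(0, c)
    return off, slice(0, n), slice(-off, -off + n)


def extract_slices(vol: Volume, view: str, spec: PreprocSpec) -> SliceStack:
    """Parse a volume into trimmed, centre-cropped 2D slices of one view."""
    if view not in VIEW_AXES:
        raise ValueError(f"unknown view {view!r}; expected one of {sorted(VIEW_AXES)}")
    axis = VIEW_AXES[view]
    data = np.moveaxis(np.asarray(vol.data), axis, 0)  # (n, a, b)
    n = data.shape[0]
    trim = math.floor(spec.trim_fraction * n)
    first, last = trim, n - trim
    if last <= first:
        raise ValueError(f"trim fraction {spec.trim_fraction} leaves no slices of {n}")
    kept = data[first:last]

    h, w = spec.crop_size
    off_a, src_a, dst_a = _crop_pad_1d(kept.shape[1], h)
    off_b, src_b, dst_b = _crop_pad_1d(kept.shape[2], w)
    out = np.zeros((kept.shape[0], h, w), dtype=kept.dtype)
    out[:, dst_a, dst_b] = kept[:, src_a, src_b]
    return SliceStack(
        slices=out,
        view=view,
        retained_range=(first, last),
        crop_offsets=(off_a, off_b),
        original_shape=vol.shape,
        spacing=vol.spacing,
    )


def restore_volume(stack: SliceStack, spacing: tuple[float, float, float] | None = None,
                   affine: np.ndarray | None = None) -> Volume:
    """Invert :func:`extract_slices`: pad the crop back and zero trimmed slices.

    The output has the stack's ``original_shape``; voxels outside the
    retained, in-frame region are zero.
    """
    axis = VIEW_AXES[stack.view]
    first, last = stack.retained_range
    shape_v = list(stack.original_shape)
    n = shape_v[axis]
    if not (0 <= first <= last <= n):
        raise ProvenanceError(f"retained range {stack.retained_range} outside [0, {n}]")
    inplane = [s for i, s in enumerate(stack.original_shape) if i != axis]

    h, w = stack.slices.shape[1:]
    _, src_a, dst_a = _crop_pad_1d(inplane[0], h)
    _, src_b, dst_b = _crop_pad_1d(inplane[1], w)

    moved = np.zeros((n, inplane[0], inplane[1]), dtype=stack.slices.dtype)
    moved[first:last, src_a, src_b] = stack.slices[:, dst_a, dst_b]
    data = np.moveaxis(moved, 0, axis)
    return Volume(data=data, spacing=spacing or stack.spacing, affine=affine)
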