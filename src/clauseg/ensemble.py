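"""Full-volume prediction by a multiview ensemble.

Each member network segments one 2D view (axial or coronal); member
probability volumes are restored to the original 3D grid and fused
voxel-wise by mean probability, then binarised with a strict ">"
threshold (default 0.5).  On binary member outputs this reduces to strict
majority voting, and ties at exactly the threshold resolve to background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .network import UNet, load_checkpoint
from .preprocess import PreprocSpec, extract_slices, restore_volume, zscore_normalize
from .volume import BinaryMask, CompatibilityError, Volume

__all__ = ["EnsembleSpec", "predict_view", "combine", "predict_subject"]


@dataclass
class EnsembleSpec:
    """Trained members (model or checkpoint path, view) plus the fusion rule."""

    members: list[tuple[UNet | str | Path, str]] = field(default_factory=list)
    aggregation: str = "mean_probability"
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.aggregation != "mean_probability":
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        for _, view in self.members:
            if view not in ("axial", "coronal"):
                raise ValueError(f"unknown view {view!r}")

    def loaded_members(self) -> list[tuple[UNet, str]]:
        out = []
        for model, view in self.members:
            if not isinstance(model, UNet):
                model = load_checkpoint(model)
            out.append((model, view))
        if out:
            ref = out[0][0].spec
            for m, _ in out[1:]:
                if m.spec.encoder_filters != ref.encoder_filters or \
                        m.spec.bottleneck_filters != ref.bottleneck_filters:
                    raise ValueError("ensemble members have differing architectures")
        return out


def predict_view(model: UNet, vol: Volume, view: str, spec: PreprocSpec) -> Volume:
    """Per-view probability volume: extract slices, forward, restore.

    ``vol`` is expected to be z-score normalised already; a clearly
    unnormalised input triggers a warning (not an error).  Trimmed slices
    of the output are exactly zero.
    """
    nonzero = vol.data[vol.data != 0]
    if nonzero.size and abs(float(nonzero.std()) - 1.0) > 0.5:
        warnings.warn("input volume does not look z-score normalised "
                      f"(nonzero-voxel std {nonzero.std():.3g})", stacklevel=2)
    from .train import predict_slices  # local import to avoid a cycle
    stack = extract_slices(vol, view, spec)
    probs = predict_slices(model, stack.slices.astype(np.float32))
    stack.slices = probs.astype(np.float64)
    return restore_volume(stack, spacing=vol.spacing, affine=vol.affine)


def combine(predictions: Sequence[Volume], spec: EnsembleSpec) -> BinaryMask:
    """Voxel-wise mean of member probabilities, binarised at the threshold."""
    if len(predictions) == 0:
        raise ValueError("combine needs at least one member prediction")
    shapes = {p.shape for p in predictions}
    if len(shapes) > 1:
        raise CompatibilityError(f"member prediction shapes differ: {shapes}")
    mean = np.mean([p.data for p in predictions], axis=0)
    ref = predictions[0]
    return BinaryMask(data=(mean > spec.threshold).astype(np.uint8),
                      spacing=ref.spacing, affine=ref.affine)


def predict_subject(ensemble: EnsembleSpec, vol: Volume, spec: PreprocSpec
                    ) -> BinaryMask:
    """Segment one raw (brain-extracted) volume with the full ensemble."""
    norm = zscore_normalize(vol)
    members = ensemble.loaded_members()
    if not members:
        raise ValueError("ensemble has no members")
    preds = [predict_view(model, norm, view, spec) for model, view in members]
    return combine(preds, ensemble)
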