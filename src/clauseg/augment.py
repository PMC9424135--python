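"""Paired affine augmentation of image/mask slices.

Training data are doubled: every (image, mask) slice pair gets exactly one
augmented copy, produced by a single random affine transform (moderate
shift, scaling, rotation and shearing about the slice centre) applied to
both members — linear interpolation for the image, nearest neighbour for
the mask so values stay binary.  Regions transformed in from outside the
frame are filled with 0, matching brain-extracted background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import CompatibilityError

__all__ = ["AugmentationSpec", "AffineTransform2D", "sample_transform", "augment_pairs"]


@dataclass(frozen=True)
class AugmentationSpec:
    """Ranges of the random transform components; all draws are uniform.

    Defaults are moderate for 200 x 200 slices containing a deep, thin
    structure: the claustrum must stay in frame.
    """

    shift_px: float = 10.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    rotation_deg: float = 10.0
    shear_deg: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.scale_range
        if not (0 < lo <= hi):
            raise ValueError(f"scale_range must satisfy 0 < min <= max, got {self.scale_range}")
        if min(self.shift_px, self.rotation_deg, self.shear_deg) < 0:
            raise ValueError("transform magnitudes must be >= 0")


@dataclass(frozen=True)
class AffineTransform2D:
    """A sampled 2D affine transform, recorded with its parameters.

    ``matrix`` is the 3x3 homogeneous forward map acting on (row, col)
    coordinates about the slice centre, composed in fixed order
    scale -> shear -> rotate -> shift.
    """

    scale: float
    shear_deg: float
    rotation_deg: float
    shift: tuple[float, float]
    matrix: np.ndarray

    def is_identity(self, tol: float = 1e-12) -> bool:
        return bool(np.allclose(self.matrix, np.eye(3), atol=tol))

    def apply(self, image: np.ndarray, order: int) -> np.ndarray:
        """Warp one slice; ``order=1`` for images, ``order=0`` for masks."""
        h, w = image.shape
        centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        # ndimage.affine_transform needs the inverse (output -> input) map
        inv = np.linalg.inv(self.matrix)
        m, t = inv[:2, :2], inv[:2, 2]
        offset = centre - m @ centre + t
        out = ndimage.affine_transform(image.astype(float), m, offset=offset,
                                       order=order, mode="constant", cval=0.0)
        if order == 0:
            out = out.astype(image.dtype)
        return out

    def apply_point(self, point: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
        """Forward-map a (row, col) point, e.g. a mask centroid."""
        centre = np.array([(shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0])
        p = np.asarray(point, dtype=float) - centre
        q = self.matrix[:2, :2] @ p + self.matrix[:2, 2]
        return q + centre


def sample_transform(spec: AugmentationSpec, rng: np.random.Generator) -> AffineTransform2D:
    """Draw one transform with every component uniform over its range."""
    scale = float(rng.uniform(*spec.scale_range))
    shear = float(rng.uniform(-spec.shear_deg, spec.shear_deg))
    rot = float(rng.uniform(-spec.rotation_deg, spec.rotation_deg))
    shift = rng.uniform(-spec.shift_px, spec.shift_px, size=2)

    s = np.diag([scale, scale, 1.0])
    sh = np.eye(3)
    sh[0, 1] = math.tan(math.radians(shear))
    th = math.radians(rot)
    r = np.array([[math.cos(th), -math.sin(th), 0.0],
                  [math.sin(th), math.cos(th), 0.0],
                  [0.0, 0.0, 1.0]])
    t = np.eye(3)
    t[:2, 2] = shift
    matrix = t @ r @ sh @ s
    return AffineTransform2D(scale=scale, shear_deg=shear, rotation_deg=rot,
                             shift=(float(shift[0]), float(shift[1])), matrix=matrix)


def augment_pairs(pairs: list[tuple[np.ndarray, np.ndarray]],
                  spec: AugmentationSpec) -> list[tuple[np.ndarray, np.ndarray]]:
    """Double a training set: originals plus one warped copy per pair.

    Each copy uses ONE shared transform for image (linear interpolation)
    and mask (nearest neighbour); output order is all originals followed
    by their augmented copies in input order.
    """
    rng = np.random.default_rng(spec.seed)
    out = list(pairs)
    for img, msk in pairs:
        img = np.asarray(img)
        msk = np.asarray(msk)
        if img.shape != msk.shape:
            raise CompatibilityError(
                f"image shape {img.shape} != mask shape {msk.shape}")
        tf = sample_transform(spec, rng)
        out.append((tf.apply(img, order=1), tf.apply(msk, order=0)))
    return out
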