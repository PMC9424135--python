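"""Synthetic MR phantoms with thin bilateral sheet targets.

The generator emulates the features of neonatal structural MRI that drive
the segmentation problem, without any real data: an ellipsoidal
brain-extracted "brain" (zero background) with a white-matter core and a
cortical ribbon whose surface undulation ("gyrification") grows with
maturity; two bilaterally symmetric thin curved sheets — sections of an
ellipsoidal shell — standing in for the claustrum; a smooth multiplicative
bias field; and additive Gaussian noise.  The foreground sheets occupy
well under 1% of brain voxels, reproducing the extreme class imbalance the
Dice loss targets.

One maturity knob ``theta`` in [0, 1] maps affinely to a scan-age analog
(theta=0 ~ 29 gestational weeks, theta=1 ~ 42 weeks) and jointly controls
gyrification amplitude, cortex/white-matter contrast and sheet contrast:
young phantoms have weaker gyrification, flatter tissue contrast and a
much fainter sheet, emulating the domain shift that degrades models
trained only on older subjects.  ``polarity="t1_like"`` inverts the
within-brain contrast to provide an adult-T1-like source domain for
transfer learning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import ndimage

from .volume import BinaryMask, SubjectRecord, Volume

__all__ = ["PhantomSpec", "RaterModel", "generate_phantom", "generate_cohort",
           "simulate_rater", "tissue_intensities", "sheet_geometry",
           "theta_to_weeks"]

# geometry constants (fractions of the grid / brain size)
_BRAIN_SEMI_FRAC = 0.42     # brain ellipsoid semi-axis as fraction of grid
_CORTEX_INNER = 0.80        # inner radius of the cortical ribbon
_SHEET_RADIUS = 0.52        # sheet shell radius as fraction of brain semi-axes
_SHEET_CAP_DEG = 35.0       # half-angle of the lateral cap around the LR axis


class PhantomSpecError(ValueError):
    pass


@dataclass(frozen=True)
class PhantomSpec:
    """All parameters of the synthetic generator."""

    grid: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    maturity: float = 1.0
    polarity: str = "t2_like"
    noise_sigma: float = 0.05
    bias_amplitude: float = 0.1
    sheet_thickness_vox: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.maturity <= 1.0:
            raise PhantomSpecError(f"maturity must be in [0,1], got {self.maturity}")
        if self.polarity not in ("t2_like", "t1_like"):
            raise PhantomSpecError(f"unknown polarity {self.polarity!r}")
        if self.sheet_thickness_vox < 1:
            raise PhantomSpecError("sheet thickness must be >= 1 voxel")
        if min(self.grid) < 32:
            raise PhantomSpecError(
                f"grid {self.grid} too small to contain the sheets; need >= 32 per axis")


@dataclass(frozen=True)
class RaterModel:
    """Simulated human rater: random boundary jitter plus a systematic
    erode/dilate tendency (in voxels; positive dilates)."""

    boundary_jitter_vox: float = 1.0
    erode_dilate_bias: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.boundary_jitter_vox < 0:
            raise ValueError("jitter must be >= 0")


def theta_to_weeks(theta: float) -> float:
    """Affine maturity -> scan-age map (29 weeks at 0, 42 weeks at 1)."""
    return 29.0 + 13.0 * float(theta)


def gyrification_amplitude(theta: float) -> float:
    """Surface undulation amplitude (fraction of brain radius) vs maturity."""
    return 0.02 + 0.10 * float(theta)


def tissue_intensities(spec: PhantomSpec) -> dict[str, float]:
    """Noise-free compartment intensities for a given maturity/polarity.

    In the T2-like target domain the sheet contrast against white matter
    shrinks from 0.35 at full maturity to 0.06 at theta=0, and the
    cortex/white-matter contrast flattens likewise.
    """
    th = spec.maturity
    vals = {
        "white_matter": 0.55,
        "cortex": 0.30 + 0.25 * (1.0 - th),
        "sheet": 0.61 + 0.29 * th,
    }
    if spec.polarity == "t1_like":
        vals = {k: 1.10 - v for k, v in vals.items()}
    return vals


def sheet_geometry(spec: PhantomSpec) -> dict[str, float]:
    """Parametric description of the sheet caps (for analytic oracles)."""
    semis = tuple(_BRAIN_SEMI_FRAC * n * _SHEET_RADIUS for n in spec.grid)
    return {
        "semi_axes_vox": semis,
        "cap_half_angle_deg": _SHEET_CAP_DEG,
        "thickness_vox": spec.sheet_thickness_vox,
    }


def _coords(grid: Sequence[int]) -> list[np.ndarray]:
    ctr = [(n - 1) / 2.0 for n in grid]
    return [np.arange(n).reshape([-1 if i == j else 1 for j in range(3)]) - ctr[i]
            for i, n in enumerate(grid)]


def _smooth_field(grid: Sequence[int], rng: np.random.Generator,
                  sigma_frac: float = 0.15) -> np.ndarray:
    """Smooth zero-mean random field, normalised to unit max amplitude."""
    field = rng.standard_normal(tuple(grid))
    field = ndimage.gaussian_filter(field, sigma=[sigma_frac * n for n in grid])
    amax = np.abs(field).max()
    return field / amax if amax > 0 else field


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, BinaryMask, float]:
    """Generate one phantom: (volume, sheet mask, scan_age_weeks).

    Fully deterministic given the spec (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.grid
    cx, cy, cz = _coords(spec.grid)
    semi = [_BRAIN_SEMI_FRAC * n for n in spec.grid]

    ux, uy, uz = cx / semi[0], cy / semi[1], cz / semi[2]
    rho = np.sqrt(ux ** 2 + uy ** 2 + uz ** 2)
    with np.errstate(invalid="ignore"):
        # angular coordinates for the gyrification proxy
        phi = np.arctan2(uy, ux)
        psi = np.arcsin(np.clip(np.where(rho > 0, uz / np.maximum(rho, 1e-12), 0.0), -1, 1))
    th = spec.maturity
    amp = gyrification_amplitude(th)
    freq = 4.0 + 6.0 * th
    phase = rng.uniform(0, 2 * math.pi, size=2)
    gyri = np.sin(freq * phi + phase[0]) * np.cos(freq * psi + phase[1])

    surface = 1.0 + amp * gyri
    brain = rho <= surface
    cortex = brain & (rho > _CORTEX_INNER * surface)

    # thin bilateral sheets: ellipsoidal shell cap around the left-right axis
    ssemi = [s * _SHEET_RADIUS for s in semi]
    vx, vy, vz = cx / ssemi[0], cy / ssemi[1], cz / ssemi[2]
    rho_s = np.sqrt(vx ** 2 + vy ** 2 + vz ** 2)
    grad = np.sqrt((vx / ssemi[0]) ** 2 + (vy / ssemi[1]) ** 2
                   + (vz / ssemi[2]) ** 2) / np.maximum(rho_s, 1e-12)
    signed_vox = (rho_s - 1.0) / np.maximum(grad, 1e-12)   # ~ voxels from shell
    lateral = np.abs(vx) / np.maximum(rho_s, 1e-12) >= math.cos(
        math.radians(_SHEET_CAP_DEG))
    sheet = (np.abs(signed_vox) <= spec.sheet_thickness_vox / 2.0) & lateral & brain
    if not sheet.any():
        raise PhantomSpecError("sheets are not containable in this grid")

    levels = tissue_intensities(spec)
    vol = np.zeros(spec.grid, dtype=np.float64)
    vol[brain] = levels["white_matter"]
    vol[cortex] = levels["cortex"]
    vol[sheet] = levels["sheet"]

    if spec.bias_amplitude > 0:
        bias = 1.0 + spec.bias_amplitude * _smooth_field(spec.grid, rng)
        vol[brain] *= bias[brain]
    if spec.noise_sigma > 0:
        noise = rng.normal(0.0, spec.noise_sigma, size=spec.grid)
        vol[brain] += noise[brain]

    volume = Volume(data=vol, spacing=spec.spacing)
    mask = BinaryMask(data=sheet.astype(np.uint8), spacing=spec.spacing,
                      affine=volume.affine)
    return volume, mask, theta_to_weeks(th)


def generate_cohort(n: int,
                    age_sampler: Optional[Callable[[np.random.Generator], float]
                                          | tuple[float, float]] = None,
                    spec: PhantomSpec = PhantomSpec(),
                    seed: int = 0) -> list[SubjectRecord]:
    """Generate ``n`` independent seeded phantoms as subject records.

    ``age_sampler`` draws maturity theta per subject: a callable taking the
    cohort RNG, a ``(lo, hi)`` uniform range, or None for the default
    uniform(0.5, 1.0) — an older-neonate cohort like the training
    population whose scan ages cluster near term.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    if age_sampler is None:
        age_sampler = (0.5, 1.0)
    if isinstance(age_sampler, tuple):
        lo, hi = age_sampler
        draw = lambda r: float(r.uniform(lo, hi))
    else:
        draw = age_sampler
    subjects = []
    for i in range(n):
        theta = float(np.clip(draw(rng), 0.0, 1.0))
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        sub_spec = replace(spec, maturity=theta, seed=sub_seed)
        volume, mask, age = generate_phantom(sub_spec)
        subjects.append(SubjectRecord(
            id=f"phantom{i:03d}", volume=volume, mask=mask, scan_age_weeks=age,
            info={"theta": theta, "seed": sub_seed,
                  "gyrification_amplitude": gyrification_amplitude(theta),
                  "polarity": spec.polarity},
        ))
    return subjects


def simulate_rater(mask: BinaryMask, rater: RaterModel) -> BinaryMask:
    """Perturb a mask the way an independent human rater would.

    The mask surface is moved by a smooth random field scaled by the
    jitter magnitude plus a systematic erode/dilate offset, applied to the
    signed Euclidean distance of each voxel to the mask boundary.  With
    zero jitter and zero bias this is the identity.
    """
    data = mask.data.astype(bool)
    if not data.any():
        raise ValueError("rater simulation needs a nonempty mask")
    if rater.boundary_jitter_vox == 0 and rater.erode_dilate_bias == 0:
        return BinaryMask(data=mask.data.copy(), spacing=mask.spacing,
                          affine=mask.affine)
    d_in = ndimage.distance_transform_edt(data)
    d_out = ndimage.distance_transform_edt(~data)
    sdist = d_out - d_in                       # negative inside, positive outside
    # voxel-centre distances never hit 0; shift by half a voxel so the
    # implied surface sits between the innermost and outermost shells
    sdist = sdist - 0.5 * np.sign(sdist)
    rng = np.random.default_rng(rater.seed)
    z = _smooth_field(mask.shape, rng, sigma_frac=0.04)
    z = z / max(z.std(), 1e-12)
    perturbed = sdist < rater.erode_dilate_bias + rater.boundary_jitter_vox * z
    return BinaryMask(data=perturbed.astype(np.uint8), spacing=mask.spacing,
                      affine=mask.affine)
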