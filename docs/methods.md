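# Methods

This note documents the models, conventions and design choices of
`clauseg`: what each stage computes, which parameters matter, what the
synthetic phantoms do and do not emulate, and the numerical details a
user would otherwise have to read out of the source.

## Problem setting

The target structure is a thin (1–3 voxel) curved gray-matter sheet, one
per hemisphere, occupying well under 1% of brain voxels in a
brain-extracted 3D MR volume at ~0.5 mm isotropic resolution.  Because
sagittal slices show the sheet nearly edge-on, segmentation operates on
2D axial and coronal slices only, with per-view networks fused in 3D.

## Preprocessing and its inverse

Three steps run before slices reach a network:

1. **Z-score normalisation over brain voxels.**  Inputs are
   brain-extracted, so exact zeros are background.  Mean and population
   standard deviation are computed over nonzero voxels only; background
   stays 0.  Including background would let brain size dominate the
   statistics.  All-zero or constant-intensity volumes raise a
   degenerate-input error.
2. **In-plane centre crop** to `crop_size` (default 200 × 200 pixels).
   Offsets are symmetric; an odd remainder crops (or pads) one extra
   pixel on the high-index side.  Slices smaller than the crop are
   zero-padded rather than rejected, so small test volumes use the same
   code path; the signed offsets are recorded (positive = crop,
   negative = pad).
3. **Slice trimming**: the first and last `floor(0.25·n)` slices along
   the view's stacking axis are removed (a 192-slice scan keeps exactly
   slices [48, 144)).  The trim is applied along each view's own
   stacking axis.

A `SliceStack` records view, retained range, crop offsets and original
shape, so postprocessing is an exact inverse: predictions are padded back
to the original in-plane size and the trimmed slice range is zeroed.  On
the retained, in-frame region the round trip is the identity, and
foreground counts are conserved whenever the foreground lies inside that
region (both properties are tested).

Volumes are reoriented to canonical RAS+ axis order on load; "axial"
(stacking axis = inferior–superior) and "coronal" (posterior–anterior)
are defined against this canonical order, not the on-disk order, which
removes any view ambiguity.  The hemisphere split defaults to the middle
index of the left–right axis and can be overridden.

## Augmentation

Training data are doubled exactly: each (image, mask) slice pair receives
one augmented copy produced by a single random affine transform applied
to both members — linear interpolation for the image, nearest neighbour
for the mask (values stay binary), zero fill outside the frame.  The
transform composes scale → shear → rotate → shift about the slice centre,
each parameter uniform in its range.  Defaults are moderate for a deep
thin structure that must stay in frame: shift ≤ 10 px, scale 0.9–1.1,
rotation ≤ 10°, shear ≤ 5°.  Elastic deformation, intensity augmentation
and flips are deliberately out of scope.

## Network

The single-view network is a U-shaped 2D encoder–decoder:

| stage        | channels | convolutions        |
|--------------|----------|---------------------|
| encoder 1    | 32       | 3×3, 3×3            |
| encoder 2    | 64       | 3×3, 3×3            |
| encoder 3    | 96       | 3×3, 3×3            |
| encoder 4    | 128      | 3×3, **4×4**        |
| bottleneck   | 256      | 3×3, 3×3            |
| decoder 4…1  | 128/96/64/32 | up ×2, concat skip, 3×3, 3×3 |
| head         | 1        | 1×1 + sigmoid       |

ReLU follows every convolution except the sigmoid head; 2×2 max pooling
separates encoder stages; the decoder upsamples by parameter-free nearest
neighbour.  This configuration — a non-doubling filter ladder with a 4×4
second convolution in the deepest encoder stage, in the style of the
published multiview claustrum / white-matter-hyperintensity family of
networks — totals exactly **2,494,529** trainable parameters at the
200 × 200 single-channel input, which is pinned by an acceptance test.
The output is a single-channel foreground probability (sigmoid) rather
than two-channel softmax; for a binary task either works and one had to
be fixed.

Odd spatial sizes are handled as in the classic Keras implementations of
this family: pooling floor-divides; on concatenation the skip tensor is
centre-cropped to the upsampled size; the decoder output is zero-padded
back to the input size before the 1×1 head.  Sizes whose bottleneck grid
would fall below 4 pixels are rejected with an explanatory error.

`NetworkSpec.test_size()` (encoder 4/8, bottleneck 16, default input
36 × 36, ~8.3k parameters) is a reduced variant for unit tests and
CPU-scale experiments; it is labelled `variant="test"` and is *not* the
published architecture.

The engine is written in NumPy (channels-last layout, convolution as k²
shifted GEMMs, hand-derived backward passes).  This keeps the package
dependency-light and bit-reproducible given the seed; the backward pass
is validated against central finite differences in the test suite.
Checkpoints are single `.npz` files embedding the architecture
specification and a format version, so they are self-describing.

## Loss and optimisation

Class imbalance is handled entirely by the soft Dice loss

    L = 1 − (2·Σ p·t + s) / (Σ p + Σ t + s),   s = 1.0,

pooled over the whole batch, with the smooth constant `s` stabilising
empty targets.  On hard predictions 1 − L matches the DSC metric as
s → 0 (tested).  No slice resampling or reweighting is used.

Optimisation is Adam (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸) at learning rate
0.0002 with batch size 60.  Budgets are fixed: 30 epochs when fine-tuning
from a pretrained checkpoint, 275 from scratch.  Validation VS and DSC
are recorded per epoch when a validation set exists but never trigger
early stopping.  Transfer learning loads all weights from the source
checkpoint and fine-tunes every layer (no freezing); the source and
target architectures must match except for input size, which a fully
convolutional network does not constrain.  All data splits are at
subject level — slices of one subject never cross a train/validation
boundary.

## Ensemble fusion

Member probability volumes (default three axial + three coronal) are
averaged voxel-wise and binarised with a strict `>` threshold at 0.5.
On binary member outputs this reduces to strict majority voting (checked
exhaustively for six members); ties at exactly the threshold resolve to
background, the conservative choice for a small structure.  The
combination is invariant to member order.  A per-direction alternative to
the pooled HD95 (below) and the threshold are the only tunables.

## Evaluation metrics

* **VS** = 100·(1 − |V_M − V_P| / (V_M + V_P)) with V a foreground voxel
  count: volume agreement ignoring location.
* **DSC** = 100·2|M ∩ P| / (|M| + |P|): spatial overlap.
* **HD95**: border voxels are foreground voxels with at least one
  face-adjacent (6-neighbourhood) background neighbour, with out-of-grid
  treated as background.  For each border voxel of M the minimum
  Euclidean distance (mm, anisotropy-aware, via exact distance
  transforms) to P's border set is computed and vice versa; HD95 is the
  95th percentile (linear interpolation between order statistics) of the
  *pooled union* of both directed sets.  Pooling matches the common
  reference implementations; a `method="max_directed"` flag switches to
  the maximum of the two per-direction percentiles.  The implementation
  agrees with an exhaustive all-pairs scan to 10⁻⁹ mm on small grids and
  scales exactly linearly with voxel spacing (both tested).

Empty-mask conventions: both empty → VS = DSC = 100 (flagged), HD95
undefined; exactly one empty → VS = DSC = 0, HD95 undefined (flagged,
not an exception, so batch evaluation keeps going and undetected-structure
cases enter failure analysis rather than distance statistics).

Paired comparisons (model vs rater, model vs model) use the two-sided
Wilcoxon signed-rank test; zero differences are discarded and the exact
null distribution is used for n ≤ 25 (checked against full sign-flip
enumeration), the normal approximation beyond.

## Synthetic phantoms

Each phantom is an ellipsoidal "brain" (semi-axes 0.42 of the grid, zero
background) containing a white-matter core, a cortical ribbon whose
surface undulation ("gyrification" proxy) has amplitude 0.02 + 0.10·θ
and angular frequency 4 + 6·θ, and two bilaterally symmetric thin sheets:
the lateral caps (half-angle 35° about the left–right axis) of an
ellipsoidal shell at 0.52 of the brain's semi-axes, `sheet_thickness_vox`
(default 2) voxels thick along the shell normal.  The mask is exactly
the sheets; bilateral symmetry is analytic, so the hemisphere split is
exactly balanced.  A smooth multiplicative bias field (amplitude 0.1)
and additive Gaussian noise (σ = 0.05) act on brain voxels only.

The maturity knob θ ∈ [0, 1] maps affinely to a scan-age analog
(29 weeks at 0, 42 at 1) and jointly controls gyrification and contrast:

| compartment  | T2-like intensity        |
|--------------|--------------------------|
| white matter | 0.55                     |
| cortex       | 0.30 + 0.25·(1 − θ)      |
| sheet        | 0.61 + 0.29·θ            |

At full maturity the sheet contrast against white matter is 0.35; at
θ = 0 it shrinks to 0.06 (about one noise standard deviation) and the
cortex/white-matter contrast flattens — emulating, in one knob, the
reduced gyrification and different contrast appearance that degrade
models trained only on older subjects.  The default cohort sampler draws
θ uniformly from [0.5, 1.0], an older-neonate training population;
experiments pass explicit ranges for young cohorts.  `t1_like` polarity
maps every compartment intensity v to 1.10 − v, inverting the
within-brain contrast as an adult-T1-like source domain for transfer
learning.

A simulated rater perturbs a mask by thresholding its signed Euclidean
boundary distance (shifted half a voxel so the implied surface lies
between voxel shells) against a smooth unit-variance noise field scaled
by a jitter magnitude, plus a systematic erode/dilate offset.  Jitter
strictly decreases agreement with the reference, and two independent
raters agree less with each other than either does with the reference —
the ordering seen in human intra-/interrater reliability.

What the phantoms do **not** emulate: MR physics (no k-space, motion,
partial volume or scanner-specific intensity distributions), real
neuroanatomy (the sheet is a parametric shell cap, not an atlas shape),
and inter-subject anatomical variability beyond seed, age and noise.
Passing the phantom-based tests therefore demonstrates that the pipeline
is correct and that its qualitative behaviours (ensemble gains, transfer
warm-start, age-domain shift) hold — not that any particular accuracy
level transfers to clinical data.

## Problem sizes used by the test suite

The end-to-end checks run at CPU scale, chosen so the whole suite stays
in the minutes range: 64³ phantom grids, a 36 × 36 crop, the reduced
test network, 15-epoch budgets, one member per view, and cohorts of 5–12
subjects, with medians over three seeds for every stochastic check.
Accuracy thresholds are not adjusted for the scaling.  The full-size
network is instantiated (parameter count, forward pass) but never
trained in the tests.

## Known limitations

* The NumPy engine is single-threaded and CPU-bound; training the
  full-size network on a real cohort is out of its intended scope.
* Exact Wilcoxon p-values require tie-free differences; with ties the
  implementation falls back to the normal approximation.
* HD95 between masks of very few voxels is dominated by voxelisation;
  the phantoms' analytic-band test bounds, but does not eliminate, this
  discretisation.
* No connected-component postfiltering or uncertainty output: the
  combined mask is reported raw.
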