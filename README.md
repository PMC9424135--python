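# clauseg — multiview CNN segmentation of the claustrum in neonatal brain MRI

The claustrum is a thin, sheet-like gray-matter structure between the
external and extreme capsules.  Segmenting it in T2-weighted neonatal MRI
is hard for classical atlas methods: it is only a few voxels thick, its
boundaries are ambiguous, and its voxels are a sub-percent fraction of the
brain (extreme class imbalance).  `clauseg` implements a complete
deep-learning pipeline for this problem, aimed at researchers who need
automated claustrum masks for large neonatal cohorts (such as the
developing Human Connectome Project) and at method developers who want a
fully testable reference implementation:

* **Multiview 2D ensemble.**  A U-shaped encoder–decoder network is
  trained per anatomical view (axial and coronal slices).  At test time
  the per-view probability maps are restored to the 3D grid and fused
  voxel-wise (mean probability, threshold 0.5; equivalent to strict
  majority voting on binary members).  The default configuration is three
  members per view.
* **Transfer learning.**  Networks can be initialised from a checkpoint
  trained on an adult T1-like source domain and fine-tuned on the
  neonatal T2 target task with a short, fixed budget (30 epochs, batch
  60, Adam at learning rate 2·10⁻⁴, Dice loss), instead of hundreds of
  epochs from scratch.
* **Evaluation suite.**  Volumetric similarity
  VS = 1 − |V_M − V_P| / (V_M + V_P), Dice similarity coefficient
  DSC = 2|M ∩ P| / (|M| + |P|), and the 95th-percentile Hausdorff
  distance HD95 over symmetric border-to-border Euclidean distances (mm,
  anisotropy-aware), plus paired Wilcoxon signed-rank comparisons and
  k-fold cross-validation, learning-curve and age-stratification
  harnesses.
* **Synthetic phantoms.**  A seeded generator produces brain-like volumes
  with two thin, bilaterally symmetric curved sheets as ground truth, a
  maturity knob that emulates the young-neonate domain shift (scan age
  29–42 gestational weeks), and an inverted-contrast T1-like variant as a
  transfer-learning source domain — so the entire pipeline is exercised
  end-to-end without any gated data.

The single-view network is implemented in a small, dependency-light NumPy
engine (hand-derived backpropagation, gradient-checked against finite
differences); the full-size configuration has exactly **2,494,529**
trainable parameters at its 200 × 200 single-channel input.

## Worked example

A CPU-scale run on synthetic phantoms (64³ voxels, reduced "test"
network, one member per view).  `run.yaml`:

```yaml
phantom:      {grid: [64, 64, 64], seed: 7}
preprocess:   {crop_size: [36, 36]}
augment:      {shift_px: 3.0, seed: 0}
network:      {input_size: [36, 36], encoder_filters: [4, 8],
               bottleneck_filters: 16, variant: test}
train:        {epochs: 15, seed: 0}
members_per_view: 1
```

```bash
clauseg simulate --config run.yaml --out train_cohort --n 8
clauseg simulate --config run.yaml --seed 99 --out test_cohort --n 2
clauseg train    --config run.yaml --cohort train_cohort --out ckpt
clauseg predict  --config run.yaml --ensemble-dir ckpt --cohort test_cohort --out pred
clauseg evaluate --config run.yaml --pred-dir pred --cohort test_cohort --out metrics.csv
```

`metrics.csv` then contains (actual output of the commands above):

```
subject_id,vs_percent,hd95_mm,dsc_percent,m_empty,p_empty
phantom000,81.06863196683555,0.5,74.5278673422386,False,False
phantom001,81.51922186197314,0.5,74.3862899490505,False,False
median(IQR),81.29392691440435,0.5,74.45707864564454,,
```

Reading the rows: the predicted sheet volume agrees with ground truth to
within ~19% (VS ≈ 81%), the 95th-percentile boundary error is half a
millimetre — one voxel at the phantoms' 0.5 mm spacing — and the spatial
overlap is DSC ≈ 74%, in the range expected for a structure this thin at
this training budget.  `clauseg evaluate --compare-dir` adds paired
two-sided Wilcoxon p-values between two prediction sets, the same test
used to compare automated segmentation against human intra- and
interrater reliability.

Every command writes its fully resolved configuration next to its
outputs; a run is reproducible from that file alone.

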