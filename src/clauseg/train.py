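"""Model training, transfer learning, cross-validation and experiments.

Training follows fixed-budget optimisation: Adam at learning rate 0.0002,
batch size 60, Dice loss, 30 epochs when fine-tuning from a pretrained
checkpoint and 275 epochs from scratch (the defaults; experiments at CPU
scale use fewer).  Validation VS/DSC are monitored per epoch when a
validation set exists but never trigger early stopping.  All data splits
are at subject level: slices of one subject never cross the
train/validation boundary.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .augment import AugmentationSpec, augment_pairs
from .ensemble import EnsembleSpec, predict_subject
from .metrics import MetricsReport, dsc, evaluate_pair, volumetric_similarity
from .network import (LossSpec, NetworkSpec, UNet, build_network,
                      dice_loss_and_grad, load_checkpoint)
from .nn import Adam
from .preprocess import PreprocSpec, extract_slices, zscore_normalize
from .volume import SubjectRecord, Volume

__all__ = ["TrainConfig", "TrainHistory", "train_model", "kfold_crossval",
           "learning_curve", "stratified_subset", "subject_slices",
           "build_training_set"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters.

    ``epochs`` defaults to the fine-tuning budget (30); from-scratch
    training uses 275.  ``pretrained`` points at a checkpoint whose
    architecture must match the requested spec.
    """

    epochs: int = 30
    batch_size: int = 60
    learning_rate: float = 2e-4
    loss: LossSpec = LossSpec()
    pretrained: Optional[str | Path] = None
    seed: int = 0
    validation_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in [0, 1)")


@dataclass
class TrainHistory:
    """Per-epoch training loss, optional validation VS/DSC, wall time."""

    loss: list[float] = field(default_factory=list)
    val_vs: list[float] = field(default_factory=list)
    val_dsc: list[float] = field(default_factory=list)
    epoch_seconds: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.loss)


def _arch_fields(spec: NetworkSpec) -> tuple:
    # input size may differ between source and target domains (the network
    # is fully convolutional); everything else must match for weight reuse
    return (spec.input_channels, spec.encoder_filters, spec.bottleneck_filters,
            spec.deep_stage_kernel)


def train_model(spec: NetworkSpec,
                data: Sequence[tuple[np.ndarray, np.ndarray]],
                config: TrainConfig,
                val_data: Optional[Sequence[tuple[np.ndarray, np.ndarray]]] = None,
                ) -> tuple[UNet, TrainHistory]:
    """Train (or fine-tune) one single-view network on slice/mask pairs.

    With ``config.pretrained`` set, initial weights are loaded from the
    checkpoint before optimisation and every layer is fine-tuned;
    otherwise initialisation is seeded random.  Returns the trained model
    and its history.
    """
    if len(data) == 0:
        raise ValueError("training data must be nonempty")
    if config.pretrained is not None:
        pre = load_checkpoint(config.pretrained)
        if _arch_fields(pre.spec) != _arch_fields(spec):
            raise ValueError(
                f"pretrained checkpoint architecture {pre.spec} does not match "
                f"requested spec {spec}")
        model = build_network(spec, seed=config.seed)
        model.set_weights(pre.get_weights())
    else:
        model = build_network(spec, seed=config.seed)

    x = np.stack([np.asarray(img, dtype=np.float32) for img, _ in data])[:, None]
    t = np.stack([np.asarray(msk, dtype=np.float32) for _, msk in data])[:, None]
    if val_data is not None and len(val_data) > 0:
        xv = np.stack([np.asarray(i, dtype=np.float32) for i, _ in val_data])[:, None]
        tv = np.stack([np.asarray(m, dtype=np.float32) for _, m in val_data])[:, None]
    else:
        xv = tv = None

    opt = Adam(model.conv_layers(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    history = TrainHistory()
    n = x.shape[0]
    for epoch in range(config.epochs):
        t0 = time.perf_counter()
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            probs = model.forward(x[idx], train=True)
            loss, grad = dice_loss_and_grad(probs, t[idx], config.loss)
            model.backward(grad)
            opt.step()
            losses.append(loss)
        history.loss.append(float(np.mean(losses)))
        if xv is not None:
            pred = predict_slices(model, xv[:, 0]) > 0.5
            history.val_vs.append(volumetric_similarity(pred, tv[:, 0] > 0.5))
            history.val_dsc.append(dsc(pred, tv[:, 0] > 0.5))
        history.epoch_seconds.append(time.perf_counter() - t0)
    return model, history


def predict_slices(model: UNet, slices: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """Forward a stack of 2D slices, returning probabilities (S, H, W)."""
    slices = np.asarray(slices, dtype=np.float32)
    out = np.empty_like(slices)
    for start in range(0, slices.shape[0], batch_size):
        batch = slices[start:start + batch_size][:, None]
        out[start:start + batch.shape[0]] = model.forward(batch, train=False)[:, 0]
    return out


def subject_slices(subject: SubjectRecord, view: str, preproc: PreprocSpec
                   ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Normalised image slices paired with mask slices for one subject."""
    if subject.mask is None:
        raise ValueError(f"subject {subject.id} has no mask")
    vol = zscore_normalize(subject.volume)
    img_stack = extract_slices(vol, view, preproc)
    mask_vol = Volume(data=subject.mask.data.astype(np.float64),
                      spacing=subject.volume.spacing, affine=subject.volume.affine)
    msk_stack = extract_slices(mask_vol, view, preproc)
    return [(img_stack.slices[i], msk_stack.slices[i])
            for i in range(img_stack.n_slices)]


def build_training_set(subjects: Sequence[SubjectRecord], view: str,
                       preproc: PreprocSpec,
                       augment: Optional[AugmentationSpec] = None
                       ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Pool (and optionally double, by augmentation) slices of many subjects."""
    pairs: list[tuple[np.ndarray, np.ndarray]] = []
    for sub in subjects:
        pairs.extend(subject_slices(sub, view, preproc))
    if augment is not None:
        pairs = augment_pairs(pairs, augment)
    return pairs


def _train_view_ensemble(train_subjects: Sequence[SubjectRecord],
                         spec: NetworkSpec, config: TrainConfig,
                         preproc: PreprocSpec,
                         views: Sequence[str],
                         augment: Optional[AugmentationSpec],
                         members_per_view: int = 1) -> EnsembleSpec:
    members = []
    for v, view in enumerate(views):
        data = build_training_set(train_subjects, view, preproc, augment)
        for m in range(members_per_view):
            cfg = TrainConfig(epochs=config.epochs, batch_size=config.batch_size,
                              learning_rate=config.learning_rate, loss=config.loss,
                              pretrained=config.pretrained,
                              seed=config.seed + 1000 * m + 97 * v)
            model, _ = train_model(spec, data, cfg)
            members.append((model, view))
    return EnsembleSpec(members=members)


def kfold_crossval(subjects: Sequence[SubjectRecord], k: int,
                   spec: NetworkSpec, config: TrainConfig,
                   preproc: PreprocSpec,
                   views: Sequence[str] = ("axial", "coronal"),
                   augment: Optional[AugmentationSpec] = None,
                   ) -> list[list[MetricsReport]]:
    """Subject-level k-fold cross-validation.

    Each subject appears in exactly one validation fold; per fold an
    ensemble (one member per view) is trained on the remaining subjects
    and evaluated on restored full volumes.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(subjects):
        raise ValueError(f"k={k} exceeds the {len(subjects)} subjects")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(subjects))
    folds = np.array_split(order, k)
    out: list[list[MetricsReport]] = []
    for f, val_idx in enumerate(folds):
        val_set = {int(i) for i in val_idx}
        train_subs = [s for i, s in enumerate(subjects) if i not in val_set]
        fold_cfg = TrainConfig(epochs=config.epochs, batch_size=config.batch_size,
                               learning_rate=config.learning_rate, loss=config.loss,
                               pretrained=config.pretrained, seed=config.seed + 10 * f)
        ens = _train_view_ensemble(train_subs, spec, fold_cfg, preproc, views, augment)
        reports = []
        for i in sorted(val_set):
            sub = subjects[i]
            pred = predict_subject(ens, sub.volume, preproc)
            reports.append(evaluate_pair(sub.mask, pred, sub.volume.spacing,
                                         subject_id=sub.id))
        out.append(reports)
    return out


def learning_curve(subjects: Sequence[SubjectRecord], sizes: Sequence[int],
                   spec: NetworkSpec, config: TrainConfig,
                   test_subjects: Sequence[SubjectRecord],
                   preproc: PreprocSpec,
                   views: Sequence[str] = ("axial", "coronal"),
                   augment: Optional[AugmentationSpec] = None) -> pd.DataFrame:
    """Performance versus training-set size, on a fixed test set.

    Training sets are nested: the model for each size is trained on a
    prefix of one seeded subject permutation, so each larger set contains
    every smaller one.  Returns a table (size, median VS, HD95, DSC).
    """
    sizes = list(sizes)
    if len(test_subjects) == 0:
        raise ValueError("test set must be nonempty")
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("sizes must be strictly increasing")
    if sizes and sizes[-1] > len(subjects):
        raise ValueError("largest size exceeds the subject pool")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(subjects))
    rows = []
    for size in sizes:
        train_subs = [subjects[int(i)] for i in order[:size]]
        ens = _train_view_ensemble(train_subs, spec, config, preproc, views, augment)
        reports = [evaluate_pair(s.mask, predict_subject(ens, s.volume, preproc),
                                 s.volume.spacing, subject_id=s.id)
                   for s in test_subjects]
        hd = [r.hd95_mm for r in reports if r.hd95_defined]
        rows.append({
            "size": size,
            "median_vs_percent": float(np.median([r.vs_percent for r in reports])),
            "median_hd95_mm": float(np.median(hd)) if hd else np.nan,
            "median_dsc_percent": float(np.median([r.dsc_percent for r in reports])),
        })
    return pd.DataFrame(rows)


def stratified_subset(subjects: Sequence[SubjectRecord],
                      age_bins: Sequence[tuple[float, float]],
                      per_bin: Sequence[int], seed: int = 0
                      ) -> list[SubjectRecord]:
    """Seeded sample meeting a per-age-bin quota (bins are [lo, hi) weeks)."""
    if len(age_bins) != len(per_bin):
        raise ValueError("age_bins and per_bin must have equal length")
    for i, (lo, hi) in enumerate(age_bins):
        for j, (lo2, hi2) in enumerate(age_bins):
            if i < j and max(lo, lo2) < min(hi, hi2):
                raise ValueError(f"age bins {i} and {j} overlap")
    rng = np.random.default_rng(seed)
    chosen: list[SubjectRecord] = []
    for (lo, hi), quota in zip(age_bins, per_bin):
        pool = [s for s in subjects
                if s.scan_age_weeks is not None and lo <= s.scan_age_weeks < hi]
        if quota > len(pool):
            raise ValueError(
                f"bin [{lo}, {hi}) holds {len(pool)} subjects, quota is {quota}")
        idx = rng.choice(len(pool), size=quota, replace=False)
        chosen.extend(pool[int(i)] for i in sorted(idx))
    return chosen
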