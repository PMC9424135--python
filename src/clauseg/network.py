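"""The single-view U-shaped segmentation network and the Dice loss.

The network is an encoder-decoder with skip connections operating on one
2D slice at a time.  The default ("full") configuration — encoder filter
ladder (32, 64, 96, 128) with two convolutions per stage and a 4x4 kernel
as the second convolution of the deepest encoder stage, a 256-filter
bottleneck, parameter-free nearest-neighbour upsampling with crop-concat
skips, and a single-channel 1x1 sigmoid head — has exactly 2,494,529
trainable parameters at its 200 x 200 single-channel input size.

Odd spatial sizes are handled as in the classic Keras implementations of
this family: pooling floor-divides, skip tensors are centre-cropped to the
upsampled size on concatenation, and the decoder output is zero-padded
back to the input size before the 1x1 head.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .nn import Adam, Conv2D, MaxPool2, ReLU, Upsample2, sigmoid

__all__ = ["NetworkSpec", "LossSpec", "UNet", "build_network", "count_parameters",
           "dice_loss", "dice_loss_and_grad", "save_checkpoint", "load_checkpoint"]

CHECKPOINT_VERSION = 1


class SpecError(ValueError):
    """Network specification is invalid for the requested input size."""


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters of the single-view network.

    The default instance is the full-size network (2,494,529 trainable
    parameters).  :meth:`test_size` returns a reduced configuration meant
    for unit tests and CPU-scale experiments only — it is NOT the
    published architecture.
    """

    input_size: tuple[int, int] = (200, 200)
    input_channels: int = 1
    encoder_filters: tuple[int, ...] = (32, 64, 96, 128)
    bottleneck_filters: int = 256
    deep_stage_kernel: int = 4
    variant: str = "full"

    @property
    def depth(self) -> int:
        return len(self.encoder_filters)

    @classmethod
    def test_size(cls, input_size: tuple[int, int] = (36, 36)) -> "NetworkSpec":
        """Reduced network for tests/CPU runs (labelled ``variant='test'``)."""
        return cls(input_size=input_size, encoder_filters=(4, 8),
                   bottleneck_filters=16, deep_stage_kernel=4, variant="test")

    def validate(self) -> None:
        if self.input_channels != 1:
            raise SpecError("only single-channel input is supported")
        if min(self.encoder_filters) < 1 or self.bottleneck_filters < 1:
            raise SpecError("filter counts must be positive")
        for dim in self.input_size:
            d = dim
            for level in range(self.depth):
                d = d // 2
            if d < 4:
                raise SpecError(
                    f"input size {self.input_size} is too small for "
                    f"{self.depth} pooling stages: the bottleneck grid would "
                    f"fall below 4 pixels; use a larger input or fewer stages")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "NetworkSpec":
        d = json.loads(s)
        d["input_size"] = tuple(d["input_size"])
        d["encoder_filters"] = tuple(d["encoder_filters"])
        return cls(**d)


@dataclass(frozen=True)
class LossSpec:
    """Dice loss configuration; ``smooth`` stabilises empty targets."""

    kind: str = "dice"
    smooth: float = 1.0

    def __post_init__(self) -> None:
        if self.kind != "dice":
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if self.smooth <= 0:
            raise ValueError("smooth must be > 0")


def dice_loss(pred: np.ndarray, target: np.ndarray,
              loss: LossSpec = LossSpec()) -> float:
    """Soft Dice loss 1 - (2*sum(p*t) + s) / (sum(p) + sum(t) + s).

    ``pred`` holds per-pixel foreground probabilities in [0, 1]; the sums
    run over all elements, so a batch is pooled into one score.
    """
    l, _ = dice_loss_and_grad(pred, target, loss, need_grad=False)
    return l


def dice_loss_and_grad(pred: np.ndarray, target: np.ndarray,
                       loss: LossSpec = LossSpec(), need_grad: bool = True
                       ) -> tuple[float, np.ndarray | None]:
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    s = loss.smooth
    num = 2.0 * float((pred * target).sum()) + s
    den = float(pred.sum() + target.sum()) + s
    l = 1.0 - num / den
    if not need_grad:
        return l, None
    grad = (num / den ** 2) - (2.0 * target) / den
    return l, grad


class _CropConcat:
    """Centre-crop the skip tensor to the upsampled size, then concat."""

    def forward(self, up: np.ndarray, skip: np.ndarray) -> np.ndarray:
        dh = skip.shape[1] - up.shape[1]
        dw = skip.shape[2] - up.shape[2]
        oh, ow = dh // 2, dw // 2
        self._off = (oh, ow)
        self._skip_shape = skip.shape
        self._split = up.shape[3]
        cropped = skip[:, oh:oh + up.shape[1], ow:ow + up.shape[2], :]
        return np.concatenate([up, cropped], axis=3)

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        c = self._split
        dup = dy[..., :c]
        dcrop = dy[..., c:]
        dskip = np.zeros(self._skip_shape, dtype=dy.dtype)
        oh, ow = self._off
        dskip[:, oh:oh + dcrop.shape[1], ow:ow + dcrop.shape[2], :] = dcrop
        return np.ascontiguousarray(dup), dskip


class UNet:
    """U-shaped 2D segmentation network with manual backprop."""

    def __init__(self, spec: NetworkSpec, seed: int = 0, dtype=np.float32):
        spec.validate()
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        f = spec.encoder_filters
        d = spec.depth

        self.enc: list[list[Conv2D]] = []
        cin = spec.input_channels
        for i in range(d):
            k2 = spec.deep_stage_kernel if i == d - 1 else 3
            a = Conv2D(cin, f[i], 3, rng, dtype)
            b = Conv2D(f[i], f[i], k2, rng, dtype)
            self.enc.append([a, b])
            cin = f[i]
        self.bottleneck = [Conv2D(cin, spec.bottleneck_filters, 3, rng, dtype),
                           Conv2D(spec.bottleneck_filters, spec.bottleneck_filters,
                                  3, rng, dtype)]
        cin = spec.bottleneck_filters
        self.dec: list[list[Conv2D]] = []
        for i in range(d - 1, -1, -1):
            a = Conv2D(cin + f[i], f[i], 3, rng, dtype)
            b = Conv2D(f[i], f[i], 3, rng, dtype)
            self.dec.append([a, b])
            cin = f[i]
        self.head = Conv2D(cin, 1, 1, rng, dtype)
        self.pool = MaxPool2()
        self.up = Upsample2()

    # -- plumbing ---------------------------------------------------------

    def conv_layers(self) -> list[Conv2D]:
        layers: list[Conv2D] = []
        for st in self.enc:
            layers.extend(st)
        layers.extend(self.bottleneck)
        for st in self.dec:
            layers.extend(st)
        layers.append(self.head)
        return layers

    def count_parameters(self) -> int:
        return sum(l.n_params() for l in self.conv_layers())

    def set_trainable(self, flag: bool) -> None:
        for l in self.conv_layers():
            l.trainable = flag

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for l in self.conv_layers():
            out.append(l.W.copy())
            out.append(l.b.copy())
        return out

    def set_weights(self, arrays: list[np.ndarray]) -> None:
        layers = self.conv_layers()
        if len(arrays) != 2 * len(layers):
            raise ValueError("weight list length mismatch")
        for i, l in enumerate(layers):
            w, b = arrays[2 * i], arrays[2 * i + 1]
            if w.shape != l.W.shape or b.shape != l.b.shape:
                raise ValueError("weight shape mismatch against architecture")
            l.W = w.astype(self.dtype).copy()
            l.b = b.astype(self.dtype).copy()

    # -- forward / backward ----------------------------------------------

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """x: (N, 1, H, W) -> per-pixel foreground probabilities (N, 1, H, W)."""
        x = np.asarray(x, dtype=self.dtype)
        h = np.ascontiguousarray(np.moveaxis(x, 1, 3))  # to (N, H, W, C)
        enc_cache = []
        skips = []
        for a, b in self.enc:
            ra, rb = ReLU(), ReLU()
            h = ra.forward(a.forward(h, keep=train), keep=train)
            h = rb.forward(b.forward(h, keep=train), keep=train)
            skips.append(h)
            pool = MaxPool2()
            h = pool.forward(h, keep=train)
            enc_cache.append((ra, rb, pool))
        bn_relus = (ReLU(), ReLU())
        h = bn_relus[0].forward(self.bottleneck[0].forward(h, keep=train), keep=train)
        h = bn_relus[1].forward(self.bottleneck[1].forward(h, keep=train), keep=train)
        dec_cache = []
        for j, (a, b) in enumerate(self.dec):
            up = Upsample2()
            h = up.forward(h)
            cc = _CropConcat()
            h = cc.forward(h, skips[len(skips) - 1 - j])
            ra, rb = ReLU(), ReLU()
            h = ra.forward(a.forward(h, keep=train), keep=train)
            h = rb.forward(b.forward(h, keep=train), keep=train)
            dec_cache.append((up, cc, ra, rb))
        # zero-pad back to the input grid before the 1x1 head
        th, tw = x.shape[2], x.shape[3]
        ph, pw = th - h.shape[1], tw - h.shape[2]
        if train:
            self._head_pad = (ph // 2, pw // 2, h.shape[1], h.shape[2])
        if ph or pw:
            h = np.pad(h, ((0, 0), (ph // 2, ph - ph // 2),
                           (pw // 2, pw - pw // 2), (0, 0)))
        z = self.head.forward(h, keep=train)
        p = sigmoid(z)
        if train:
            self._probs = p
            self._enc_cache = enc_cache
            self._bn_relus = bn_relus
            self._dec_cache = dec_cache
        return np.moveaxis(p, 3, 1)

    def backward(self, dprob: np.ndarray) -> None:
        """Accumulate parameter gradients from dL/dprob of the last forward."""
        p = self._probs
        dprob = np.ascontiguousarray(np.moveaxis(np.asarray(dprob), 1, 3))
        dz = (dprob * p * (1.0 - p)).astype(self.dtype)
        dh = self.head.backward(dz)
        oh, ow, hh, ww = self._head_pad
        dh = dh[:, oh:oh + hh, ow:ow + ww, :]

        d = self.spec.depth
        dskips: dict[int, np.ndarray] = {}
        for j in range(len(self.dec) - 1, -1, -1):
            a, b = self.dec[j]
            up, cc, ra, rb = self._dec_cache[j]
            dh = b.backward(rb.backward(dh))
            dh = a.backward(ra.backward(dh))
            dup, dskip = cc.backward(dh)
            dskips[d - 1 - j] = dskip
            dh = up.backward(dup)
        dh = self.bottleneck[1].backward(self._bn_relus[1].backward(dh))
        dh = self.bottleneck[0].backward(self._bn_relus[0].backward(dh))
        for i in range(d - 1, -1, -1):
            a, b = self.enc[i]
            ra, rb, pool = self._enc_cache[i]
            dh = pool.backward(dh) + dskips[i]
            dh = b.backward(rb.backward(dh))
            dh = a.backward(ra.backward(dh))
        self._probs = None
        self._enc_cache = self._bn_relus = self._dec_cache = None


def build_network(spec: NetworkSpec, seed: int = 0, dtype=np.float32) -> UNet:
    """Instantiate the network with seeded, reproducible initial weights."""
    return UNet(spec, seed=seed, dtype=dtype)


def count_parameters(model: UNet) -> int:
    """Total size of all trainable weight and bias tensors."""
    return model.count_parameters()


def save_checkpoint(model: UNet, path: str | Path) -> None:
    """Write a self-describing checkpoint (architecture spec + weights)."""
    arrays = {f"arr_{i}": a for i, a in enumerate(model.get_weights())}
    np.savez(str(path), spec=model.spec.to_json(),
             version=CHECKPOINT_VERSION, **arrays)


def load_checkpoint(path: str | Path, dtype=np.float32) -> UNet:
    with np.load(str(path), allow_pickle=False) as z:
        spec = NetworkSpec.from_json(str(z["spec"]))
        n = sum(1 for k in z.files if k.startswith("arr_"))
        arrays = [z[f"arr_{i}"] for i in range(n)]
    model = UNet(spec, seed=0, dtype=dtype)
    model.set_weights(arrays)
    return model
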