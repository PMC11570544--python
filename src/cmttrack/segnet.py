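"""The segmentation unit: a compact BN-bearing encoder-decoder producing
per-pixel foreground probabilities, trained on the source domain with a soft
Dice loss, with encoder taps exposing a 1/8, 1/16, 1/32 feature pyramid for
the tracking heads.

Downsampling uses 2x2 stride-2 convolutions (no padding), so the pyramid map
at ratio r has spatial size exactly floor(H/r) x floor(W/r).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .nn import (Adam, BatchNorm2d, Conv2d, ConvBNReLU, Module, Tensor,
                 as_tensor, concat, upsample_to)

__all__ = [
    "SegModel", "TrainConfig", "FeaturePyramid", "soft_dice_loss",
    "train_source", "predict_mask", "extract_pyramid", "save_model",
    "load_model",
]

MIN_IMAGE_SIZE = 32


@dataclass
class TrainConfig:
    """Source-domain training settings (Adam, no augmentation)."""

    epochs: int = 100
    learning_rate: float = 1e-4
    batch_size: int = 4
    train_split: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.train_split < 1.0:
            raise ValueError("train_split must be in (0, 1)")


@dataclass
class FeaturePyramid:
    """Feature maps at 1/8, 1/16 and 1/32 of the input size."""

    maps: dict  # ratio -> Tensor of shape (N, C_r, floor(H/r), floor(W/r))

    @property
    def channels(self):
        return {r: t.shape[1] for r, t in self.maps.items()}


class _Down(Module):
    """2x2 stride-2 conv + BN + ReLU: exact floor(H/2) downsampling."""

    def __init__(self, cin, cout, *, rng):
        super().__init__()
        self.conv = Conv2d(cin, cout, 2, stride=2, padding=0, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)

    def __call__(self, x):
        return self.bn(self.conv(x)).relu()


class SegModel(Module):
    """Encoder-decoder with skip connections; every conv is followed by BN.

    Parameters partition exactly into BN affine (gamma, beta) vs everything
    else, which is what the test-time adaptation updates vs freezes.
    """

    def __init__(self, base_channels: int = 8, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        c = base_channels
        self.base_channels = c
        ch = {1: c, 2: 2 * c, 4: 2 * c, 8: 4 * c, 16: 4 * c, 32: 4 * c}
        self.channel_spec = ch
        self.stem = ConvBNReLU(1, ch[1], rng=rng)
        self.down1, self.enc1 = _Down(ch[1], ch[2], rng=rng), ConvBNReLU(ch[2], ch[2], rng=rng)
        self.down2, self.enc2 = _Down(ch[2], ch[4], rng=rng), ConvBNReLU(ch[4], ch[4], rng=rng)
        self.down3, self.enc3 = _Down(ch[4], ch[8], rng=rng), ConvBNReLU(ch[8], ch[8], rng=rng)
        self.down4, self.enc4 = _Down(ch[8], ch[16], rng=rng), ConvBNReLU(ch[16], ch[16], rng=rng)
        self.down5, self.enc5 = _Down(ch[16], ch[32], rng=rng), ConvBNReLU(ch[32], ch[32], rng=rng)
        self.dec16 = ConvBNReLU(ch[32] + ch[16], ch[16], rng=rng)
        self.dec8 = ConvBNReLU(ch[16] + ch[8], ch[8], rng=rng)
        self.dec4 = ConvBNReLU(ch[8] + ch[4], ch[4], rng=rng)
        self.dec2 = ConvBNReLU(ch[4] + ch[2], ch[2], rng=rng)
        self.dec1 = ConvBNReLU(ch[2] + ch[1], ch[1], rng=rng)
        self.head = Conv2d(ch[1], 1, 1, rng=rng)

    def forward(self, x, return_pyramid: bool = False):
        """x: (N, 1, H, W) array or Tensor -> foreground probability
        (N, 1, H, W); optionally also the encoder pyramid."""
        x = as_tensor(x)
        s1 = self.stem(x)
        e2 = self.enc1(self.down1(s1))
        e4 = self.enc2(self.down2(e2))
        e8 = self.enc3(self.down3(e4))
        e16 = self.enc4(self.down4(e8))
        e32 = self.enc5(self.down5(e16))
        d16 = self.dec16(concat([upsample_to(e32, e16.shape[2:]), e16], axis=1))
        d8 = self.dec8(concat([upsample_to(d16, e8.shape[2:]), e8], axis=1))
        d4 = self.dec4(concat([upsample_to(d8, e4.shape[2:]), e4], axis=1))
        d2 = self.dec2(concat([upsample_to(d4, e2.shape[2:]), e2], axis=1))
        d1 = self.dec1(concat([upsample_to(d2, s1.shape[2:]), s1], axis=1))
        prob = self.head(d1).sigmoid()
        if return_pyramid:
            return prob, FeaturePyramid({8: e8, 16: e16, 32: e32})
        return prob

    __call__ = forward


def _to_batch(images) -> np.ndarray:
    """Accept an HxW image, a list of HxW images, or an (N,1,H,W) array."""
    arr = np.asarray(images, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[:, None]
    return arr


def soft_dice_loss(pred, target, eps: float = 1e-6):
    """1 - (2 sum(p*t) + eps) / (sum(p) + sum(t) + eps).

    Works on plain arrays (returns float) and on autodiff tensors (returns a
    differentiable scalar tensor).
    """
    if isinstance(pred, Tensor):
        t = as_tensor(np.asarray(target, dtype=np.float64))
        if pred.shape != t.shape:
            raise ValueError(f"shape mismatch {pred.shape} vs {t.shape}")
        inter = (pred * t).sum()
        return 1.0 - (2.0 * inter + eps) / (pred.sum() + t.sum() + eps)
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    return float(1.0 - (2.0 * (pred * target).sum() + eps)
                 / (pred.sum() + target.sum() + eps))


def train_source(model: SegModel, data, cfg: TrainConfig,
                 log_path: str | None = None) -> list[float]:
    """Train on labelled source images (X_s, Y_s) with soft Dice loss.

    Returns the per-epoch mean loss curve (also written as CSV if a log path
    is given).  Deterministic for a fixed config seed.
    """
    images, masks = data
    x = _to_batch(images)
    y = _to_batch([(np.asarray(m) > 0).astype(np.float64) for m in masks])
    if x.shape[0] == 0:
        raise ValueError("empty source dataset")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    model.train()
    history = []
    n = x.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            pred = model(Tensor(x[idx]))
            loss = soft_dice_loss(pred, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
    model.eval()
    if log_path:
        with open(log_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "loss"])
            for i, v in enumerate(history):
                writer.writerow([i, v])
    return history


def predict_mask(model: SegModel, image) -> np.ndarray:
    """Foreground probability map for one image (eval mode, deterministic)."""
    model.eval()
    prob = model(Tensor(_to_batch(image)))
    return prob.data[0, 0]


def extract_pyramid(model: SegModel, image) -> FeaturePyramid:
    """Encoder feature maps at 1/8, 1/16, 1/32 (shared with predict_mask)."""
    x = _to_batch(image)
    if x.shape[2] < MIN_IMAGE_SIZE or x.shape[3] < MIN_IMAGE_SIZE:
        raise ValueError(f"image must be at least {MIN_IMAGE_SIZE} px per side")
    model.eval()
    _, pyr = model(Tensor(x), return_pyramid=True)
    return pyr


def save_model(model: SegModel, path: str) -> None:
    state = model.state_dict()
    np.savez(path, base_channels=model.base_channels, **state)


def load_model(path: str) -> SegModel:
    data = np.load(path, allow_pickle=False)
    model = SegModel(base_channels=int(data["base_channels"]))
    model.load_state_dict({k: data[k] for k in data.files if k != "base_channels"})
    return model
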