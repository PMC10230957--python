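"""SRGAN-style 4x super-resolution and the PSNR/SSIM quality metrics.

The generator follows the classic single-image SR layout: an input conv
+ ReLU, a stack of residual blocks (two 3x3 convs each with a residual
edge), a post-residual conv with a global skip from the first features,
and two sub-pixel (pixel-shuffle) x2 upsampling stages for the 4x
factor. The discriminator is a strided conv stack with leaky ReLUs
ending in a single realism logit. Training alternates a discriminator
step and a generator step per batch; the generator loss is a content
term (pixel MSE or feature-space MSE through a small fixed random
convolutional extractor) plus a weighted adversarial term. The feature
extractor stands in for pretrained-classifier features so the package
has no weight downloads; it is a design choice, not an approximation of
a specific network.

Enhancement operates on the RGB bands only; multispectral rasters are
never enhanced.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from skimage.metrics import structural_similarity

from . import nn
from .nn.layers import collect_params, get_state, set_state

__all__ = ["SRGANConfig", "SRModelHandle", "QualityReport", "train_srgan",
           "enhance_image", "psnr", "ssim", "nearest_upsample"]


@dataclass(frozen=True)
class SRGANConfig:
    upscale_factor: int = 4
    n_residual_blocks: int = 2
    base_channels: int = 16
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 4
    adversarial_weight: float = 1e-3
    perceptual_source: str = "feature_net"  # or "pixel_mse"
    in_channels: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        f = self.upscale_factor
        if f < 1 or (f & (f - 1)):
            raise ValueError(f"upscale_factor must be a power of 2, got {f}")
        if self.adversarial_weight < 0:
            raise ValueError("adversarial_weight must be >= 0")
        if self.perceptual_source not in ("feature_net", "pixel_mse"):
            raise ValueError(f"unknown perceptual_source {self.perceptual_source!r}")


class _Generator:
    def __init__(self, cfg: SRGANConfig, rng: np.random.Generator):
        c = cfg.base_channels
        self.inp = nn.Sequential(nn.Conv2d(cfg.in_channels, c, 3, rng=rng), nn.ReLU())
        self.blocks = [
            nn.Sequential(nn.Conv2d(c, c, 3, rng=rng), nn.ReLU(),
                          nn.Conv2d(c, c, 3, rng=rng))
            for _ in range(cfg.n_residual_blocks)
        ]
        self.post = nn.Conv2d(c, c, 3, rng=rng)
        n_up = int(np.log2(cfg.upscale_factor))
        self.ups = [
            nn.Sequential(nn.Conv2d(c, 4 * c, 3, rng=rng), nn.PixelShuffle(2), nn.ReLU())
            for _ in range(n_up)
        ]
        self.out = nn.Conv2d(c, cfg.in_channels, 3, rng=rng)
        # zero-init the residual head so the untrained generator is exactly
        # the nearest-upsampled input; training can only sharpen from there
        self.out.W.value[...] = 0.0
        self.factor = cfg.upscale_factor
        self._modules = [self.inp, *self.blocks, self.post, *self.ups, self.out]

    def params(self):
        return collect_params(*self._modules)

    def forward(self, x):
        f0 = self.inp.forward(x)
        f = f0
        for blk in self.blocks:
            f = f + blk.forward(f)          # residual edge
        f = self.post.forward(f) + f0       # global skip over the blocks
        for up in self.ups:
            f = up.forward(f)
        # global residual learning: predict the correction to the
        # nearest-upsampled input rather than the image from scratch
        base = x.repeat(self.factor, axis=2).repeat(self.factor, axis=3)
        return self.out.forward(f) + base

    def backward(self, dy):
        d = self.out.backward(dy)
        for up in self.ups[::-1]:
            d = up.backward(d)
        d_f0 = d                             # global skip branch
        d = self.post.backward(d)
        for blk in self.blocks[::-1]:
            d = d + blk.backward(d)          # residual edge
        return self.inp.backward(d + d_f0)


class _Discriminator:
    def __init__(self, cfg: SRGANConfig, rng: np.random.Generator):
        c = cfg.base_channels
        self.net = nn.Sequential(
            nn.Conv2d(cfg.in_channels, c, 3, stride=2, pad=1, rng=rng), nn.LeakyReLU(),
            nn.Conv2d(c, c, 3, stride=2, pad=1, rng=rng), nn.LeakyReLU(),
            nn.Conv2d(c, 2 * c, 3, stride=2, pad=1, rng=rng), nn.LeakyReLU(),
            nn.Conv2d(2 * c, 1, 1, rng=rng),
            nn.GlobalMean(),
        )

    def params(self):
        return self.net.params()

    def forward(self, x):
        return self.net.forward(x)

    def backward(self, dy):
        return self.net.backward(dy)


class _FeatureNet:
    """Small fixed random conv stack used as a perceptual feature space."""

    def __init__(self, cfg: SRGANConfig, rng: np.random.Generator):
        c = cfg.base_channels
        self.net = nn.Sequential(
            nn.Conv2d(cfg.in_channels, c, 3, rng=rng), nn.ReLU(),
            nn.Conv2d(c, c, 3, stride=2, pad=1, rng=rng), nn.ReLU(),
        )

    def forward(self, x):
        return self.net.forward(x)

    def backward_input(self, dy):
        d = self.net.backward(dy)
        for p in self.net.params():          # weights stay frozen
            p.grad[...] = 0
        return d


@dataclass
class SRModelHandle:
    """Trained generator plus per-epoch generator/discriminator losses."""

    generator: _Generator
    config: SRGANConfig
    history: dict[str, list[float]]

    def save(self, path: str | Path) -> None:
        state = {f"p{i}": v for i, v in enumerate(get_state(self.generator.params()))}
        np.savez(Path(path), __config__=json.dumps(asdict(self.config)),
                 __history__=json.dumps(self.history), **state)

    @classmethod
    def load(cls, path: str | Path) -> "SRModelHandle":
        data = np.load(Path(path), allow_pickle=False)
        config = SRGANConfig(**json.loads(str(data["__config__"])))
        history = json.loads(str(data["__history__"]))
        gen = _Generator(config, np.random.default_rng(config.seed))
        n = len(gen.params())
        set_state(gen.params(), [data[f"p{i}"] for i in range(n)])
        return cls(generator=gen, config=config, history=history)


@dataclass(frozen=True)
class QualityReport:
    psnr_db: float
    ssim: float
    n_images: int
    max_val: float = 1.0


def _to_nchw(image: np.ndarray) -> np.ndarray:
    if image.ndim == 2:
        image = image[:, :, None]
    return image.transpose(2, 0, 1).astype(np.float32)


def train_srgan(pairs, config: SRGANConfig) -> SRModelHandle:
    """Alternating adversarial training on (low-res, high-res) pairs.

    Each step trains the discriminator first (real vs generated), then
    the generator against the content loss plus ``adversarial_weight``
    times the non-saturating adversarial loss.
    """
    if not pairs:
        raise ValueError("train_srgan needs at least one (low, high) pair")
    f = config.upscale_factor
    xs, ys = [], []
    for lo, hi in pairs:
        lo_n, hi_n = _to_nchw(lo), _to_nchw(hi)
        if (lo_n.shape[1] * f, lo_n.shape[2] * f) != hi_n.shape[1:]:
            raise ValueError(
                f"pair shapes {lo_n.shape[1:]} -> {hi_n.shape[1:]} do not match "
                f"upscale factor {f}"
            )
        if lo_n.shape[0] != config.in_channels:
            raise ValueError(
                f"pair has {lo_n.shape[0]} channels, config.in_channels={config.in_channels}"
            )
        xs.append(lo_n)
        ys.append(hi_n)
    x = np.stack(xs)
    y = np.stack(ys)

    root = np.random.default_rng(config.seed)
    gen = _Generator(config, np.random.default_rng(int(root.integers(2**31))))
    disc = _Discriminator(config, np.random.default_rng(int(root.integers(2**31))))
    feat = (_FeatureNet(config, np.random.default_rng(int(root.integers(2**31))))
            if config.perceptual_source == "feature_net" else None)
    opt_g = nn.Adam(gen.params(), lr=config.learning_rate)
    opt_d = nn.Adam(disc.params(), lr=config.learning_rate)
    rng = np.random.default_rng(int(root.integers(2**31)))

    n = len(pairs)
    bs = max(1, config.batch_size)
    history = {"g_loss": [], "d_loss": []}
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        g_sum = d_sum = 0.0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            xb, yb = x[idx], y[idx]
            fake = gen.forward(xb)

            # --- discriminator step (generator frozen) ---
            logits_real = disc.forward(yb)
            loss_r, grad_r = nn.bce_with_logits(logits_real, np.ones(len(idx)))
            opt_d.zero_grad()
            disc.backward(grad_r)
            logits_fake = disc.forward(fake)
            loss_f, grad_f = nn.bce_with_logits(logits_fake, np.zeros(len(idx)))
            disc.backward(grad_f)
            opt_d.step()
            d_sum += (loss_r + loss_f) * len(idx)

            # --- generator step ---
            fake = gen.forward(xb)
            if feat is None:
                c_loss, d_fake = nn.mse_loss(fake, yb)
            else:
                fy = feat.forward(yb)
                fx = feat.forward(fake)
                c_loss, d_feat = nn.mse_loss(fx, fy)
                d_fake = feat.backward_input(d_feat)
            g_loss = c_loss
            if config.adversarial_weight > 0:
                logits_fake = disc.forward(fake)
                a_loss, grad_a = nn.bce_with_logits(logits_fake, np.ones(len(idx)))
                for p in disc.params():
                    p.grad[...] = 0
                d_adv = disc.backward(grad_a)
                for p in disc.params():
                    p.grad[...] = 0
                d_fake = d_fake + config.adversarial_weight * d_adv.astype(d_fake.dtype)
                g_loss = c_loss + config.adversarial_weight * a_loss
            opt_g.zero_grad()
            gen.backward(d_fake.astype(np.float32))
            opt_g.step()
            g_sum += g_loss * len(idx)
        history["g_loss"].append(g_sum / n)
        history["d_loss"].append(d_sum / n)
    return SRModelHandle(generator=gen, config=config, history=history)


def enhance_image(image: np.ndarray, model: SRModelHandle) -> np.ndarray:
    """Upscale one (h, w[, C]) raster by the trained factor; output in [0, 1]."""
    squeeze = image.ndim == 2
    x = _to_nchw(image)[None]
    if x.shape[1] != model.config.in_channels:
        raise ValueError(
            f"image has {x.shape[1]} channels, model expects {model.config.in_channels}"
        )
    y = model.generator.forward(x)[0]
    y = np.clip(y, 0.0, 1.0).transpose(1, 2, 0)
    return y[:, :, 0] if squeeze else y


def nearest_upsample(image: np.ndarray, factor: int) -> np.ndarray:
    """Nearest-neighbor baseline used for quality comparisons."""
    return image.repeat(factor, axis=0).repeat(factor, axis=1)


def psnr(a: np.ndarray, b: np.ndarray, max_val: float = 1.0) -> float:
    """Peak signal-to-noise ratio 10*log10(MAX^2 / MSE) in dB.

    Identical images return ``inf`` (the documented zero-MSE sentinel).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    if not max_val > 0:
        raise ValueError("max_val must be positive")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(max_val**2 / mse))


def ssim(a: np.ndarray, b: np.ndarray, max_val: float = 1.0) -> float:
    """Windowed structural similarity (channel-mean for multichannel)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    kwargs = {"data_range": max_val}
    if a.ndim == 3:
        kwargs["channel_axis"] = 2
    return float(structural_similarity(a, b, **kwargs))
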