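"""Encoder-decoder (UNet-style) semantic segmentation of plant canopies.

The network is a symmetric encoder-decoder with skip connections: each
level is a double 3x3-conv block, downsampling is 2x2 max pooling,
upsampling is nearest-neighbor followed by a 3x3 conv ("up-conv"), and
the decoder concatenates the matching encoder feature map before its
conv block. The printed layer budget of 10 convolutions is realized as a
2-level network (4 encoder + 2 bridge + 4 decoder 3x3 convs); the 1x1
class head and the two up-convs sit outside that count. Training
minimizes per-pixel categorical cross entropy with Adam and no
pretrained weights; the validation partition drives epoch selection
(best validation loss is checkpointed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .nn.layers import Param, collect_params, get_state, set_state
from .tiling import TileSet, one_hot_encode, to_semantic

__all__ = ["UNetConfig", "SegModelHandle", "UNet", "train_unet", "predict_mask",
           "pixel_accuracy"]


@dataclass(frozen=True)
class UNetConfig:
    """Defaults follow the published training recipe (10 conv layers,
    batch 2, learning rate 1e-5, 120 epochs); desk-scale runs shrink
    epochs/filters and raise the learning rate via the config file."""

    in_channels: int = 3
    class_count: int = 2
    conv_layer_count: int = 10
    base_filters: int = 16
    batch_size: int = 2
    learning_rate: float = 1e-5
    epochs: int = 120
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.in_channels not in (3, 5):
            raise ValueError(f"in_channels must be 3 or 5, got {self.in_channels}")
        if self.class_count < 2:
            raise ValueError("class_count must be >= 2")
        if self.conv_layer_count % 2:
            raise ValueError("conv_layer_count must be even (symmetric encoder/decoder)")
        if (self.conv_layer_count - 2) % 4:
            raise ValueError(
                "conv_layer_count must be 4*levels + 2 (double-conv blocks); "
                f"got {self.conv_layer_count}"
            )

    @property
    def levels(self) -> int:
        return (self.conv_layer_count - 2) // 4


def _double_conv(cin: int, cout: int, rng) -> nn.Sequential:
    return nn.Sequential(
        nn.Conv2d(cin, cout, 3, rng=rng), nn.ReLU(),
        nn.Conv2d(cout, cout, 3, rng=rng), nn.ReLU(),
    )


class UNet:
    """Explicit-backprop UNet; see module docstring for the topology."""

    def __init__(self, config: UNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f = config.base_filters
        L = config.levels
        self.enc = []
        self.pools = []
        cin = config.in_channels
        for i in range(L):
            cout = f * 2 ** i
            self.enc.append(_double_conv(cin, cout, rng))
            self.pools.append(nn.MaxPool2())
            cin = cout
        self.bridge = nn.Sequential(
            nn.Conv2d(cin, f * 2 ** L, 3, rng=rng), nn.ReLU(),
            nn.Conv2d(f * 2 ** L, f * 2 ** L, 3, rng=rng), nn.ReLU(),
            nn.Dropout(config.dropout, rng=np.random.default_rng(config.seed + 1)),
        )
        self.ups = []
        self.dec = []
        ch = f * 2 ** L
        for i in reversed(range(L)):
            cout = f * 2 ** i
            self.ups.append(nn.Sequential(
                nn.UpsampleNearest2(), nn.Conv2d(ch, cout, 3, rng=rng), nn.ReLU()
            ))
            self.dec.append(_double_conv(2 * cout, cout, rng))
            ch = cout
        self.head = nn.Conv2d(ch, config.class_count, 1, rng=rng)
        self._modules = [*self.enc, self.bridge, *self.ups, *self.dec, self.head]

    # -- plumbing ---------------------------------------------------------
    def params(self) -> list[Param]:
        return collect_params(*self._modules)

    def set_training(self, flag: bool) -> None:
        for m in self._modules:
            if isinstance(m, nn.Sequential):
                m.set_training(flag)

    def state(self):
        return get_state(self.params())

    def load_state(self, state) -> None:
        set_state(self.params(), state)

    # -- forward/backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        L = self.config.levels
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bridge.forward(x)
        self._skip_channels = []
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = dec.forward(x)
        return self.head.forward(x)

    def backward(self, dy: np.ndarray) -> None:
        dy = self.head.backward(dy)
        # decoder stages from the output back toward the bridge
        dskips = []
        for up, dec, c_skip in zip(self.ups[::-1], self.dec[::-1],
                                   self._skip_channels[::-1]):
            d = dec.backward(dy)
            dskips.append(d[:, :c_skip])
            dy = up.backward(d[:, c_skip:])
        dy = self.bridge.backward(dy)
        # dskips were collected shallowest-first; the encoder unwinds
        # deepest-first, so pair them reversed
        for blk, pool, dskip in zip(self.enc[::-1], self.pools[::-1],
                                    dskips[::-1]):
            dy = pool.backward(dy) + dskip
            dy = blk.backward(dy)


@dataclass
class SegModelHandle:
    """Trained segmenter plus its per-epoch training history."""

    model: UNet
    config: UNetConfig
    history: dict[str, list[float]]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        state = {f"p{i}": v for i, v in enumerate(self.model.state())}
        np.savez(
            path,
            __config__=json.dumps(asdict(self.config)),
            __history__=json.dumps(self.history),
            **state,
        )

    @classmethod
    def load(cls, path: str | Path) -> "SegModelHandle":
        data = np.load(path, allow_pickle=False)
        config = UNetConfig(**json.loads(str(data["__config__"])))
        history = json.loads(str(data["__history__"]))
        model = UNet(config)
        n = len(model.params())
        model.load_state([data[f"p{i}"] for i in range(n)])
        return cls(model=model, config=config, history=history)


def _to_batch(tiles, in_channels: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack tiles into NCHW inputs and NKHW one-hot targets."""
    xs, ys = [], []
    for t in tiles:
        img = t.image
        if img.ndim == 2:
            img = img[:, :, None]
        if img.shape[2] != in_channels:
            raise ValueError(
                f"tile has {img.shape[2]} channels, model expects {in_channels} "
                "(band order R,G,B[,RE,NIR])"
            )
        xs.append(img.transpose(2, 0, 1))
        ys.append(one_hot_encode(to_semantic(t.mask), 2).transpose(2, 0, 1))
    return (np.stack(xs).astype(np.float32), np.stack(ys).astype(np.float32))


def train_unet(tileset: TileSet, config: UNetConfig) -> SegModelHandle:
    """Train on the ``train`` partition, monitor the ``validation`` one.

    Records per-epoch loss and pixel accuracy for both partitions and
    restores the weights of the epoch with the lowest validation loss.
    """
    train_tiles = tileset.partition("train")
    if not train_tiles:
        raise ValueError("training partition is empty")
    val_tiles = tileset.partition("validation")
    x_tr, y_tr = _to_batch(train_tiles, config.in_channels)
    x_va, y_va = _to_batch(val_tiles, config.in_channels) if val_tiles else (None, None)

    model = UNet(config)
    opt = nn.Adam(model.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history = {"train_loss": [], "train_accuracy": [],
               "val_loss": [], "val_accuracy": []}
    best = (np.inf, None)
    n = len(train_tiles)
    bs = max(1, config.batch_size)
    for _epoch in range(config.epochs):
        model.set_training(True)
        order = rng.permutation(n)
        ep_loss, ep_correct, ep_pix = 0.0, 0, 0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            xb, yb = x_tr[idx], y_tr[idx]
            logits = model.forward(xb)
            loss, grad = nn.softmax_cross_entropy(logits, yb)
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            ep_loss += loss * len(idx)
            pred = logits.argmax(axis=1)
            ep_correct += int((pred == yb.argmax(axis=1)).sum())
            ep_pix += pred.size
        history["train_loss"].append(ep_loss / n)
        history["train_accuracy"].append(ep_correct / ep_pix)
        if x_va is not None:
            vl, va = _evaluate(model, x_va, y_va, bs)
            history["val_loss"].append(vl)
            history["val_accuracy"].append(va)
            if vl < best[0]:
                best = (vl, model.state())
        else:
            history["val_loss"].append(float("nan"))
            history["val_accuracy"].append(float("nan"))
    if best[1] is not None:
        model.load_state(best[1])
    model.set_training(False)
    return SegModelHandle(model=model, config=config, history=history)


def _evaluate(model: UNet, x: np.ndarray, y: np.ndarray, bs: int):
    model.set_training(False)
    loss_sum, correct, pix = 0.0, 0, 0
    for start in range(0, len(x), bs):
        xb, yb = x[start : start + bs], y[start : start + bs]
        logits = model.forward(xb)
        loss, _ = nn.softmax_cross_entropy(logits, yb)
        loss_sum += loss * len(xb)
        pred = logits.argmax(axis=1)
        correct += int((pred == yb.argmax(axis=1)).sum())
        pix += pred.size
    return loss_sum / len(x), correct / pix


def predict_mask(handle: SegModelHandle, tile_image: np.ndarray) -> np.ndarray:
    """Per-pixel argmax class for one (h, w, C) tile.

    Ties break toward the lower class index (argmax convention).
    """
    cfg = handle.config
    img = tile_image
    if img.ndim == 2:
        img = img[:, :, None]
    h, w, c = img.shape
    if c != cfg.in_channels:
        raise ValueError(f"image has {c} channels, model expects {cfg.in_channels}")
    div = 2 ** cfg.levels
    if h % div or w % div:
        raise ValueError(
            f"image size {(h, w)} not divisible by {div}; pad to "
            f"({-(-h // div) * div}, {-(-w // div) * div})"
        )
    handle.model.set_training(False)
    logits = handle.model.forward(img.transpose(2, 0, 1)[None].astype(np.float32))
    return logits[0].argmax(axis=0).astype(np.int32)


def pixel_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of pixels whose labels agree."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    return float(np.mean(pred == truth))
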