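"""Fixed-size tiling of stitched scenes, augmentation and the 8:1:1 split.

Scenes are cut on a zero-overlap grid from top to bottom and left to
right; ragged edge strips that cannot fill a tile are dropped rather than
padded. Training tiles may be expanded with the closed set of axis
symmetries {identity, hflip, vflip, transpose}; augmented tiles always
inherit the split of their parent tile so no derived view of a test or
validation tile can leak into training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .scene import SceneBundle

__all__ = [
    "Tile",
    "TileSet",
    "crop_tiles",
    "augment_tiles",
    "split_dataset",
    "one_hot_encode",
    "to_semantic",
]

AUGMENTATION_TAGS = ("identity", "hflip", "vflip", "transpose")


@dataclass(frozen=True)
class Tile:
    image: np.ndarray            # (h, w, C) float
    mask: np.ndarray             # (h, w) int
    origin: tuple[int, int]      # (row, col) of the top-left corner in the scene
    augmentation_tag: str = "identity"

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("tile image and mask dimensions differ")
        if self.augmentation_tag not in AUGMENTATION_TAGS:
            raise ValueError(f"unknown augmentation_tag {self.augmentation_tag!r}")


@dataclass
class TileSet:
    """Tiles plus their train/test/validation assignment."""

    tiles: list[Tile]
    split: list[str]             # parallel to tiles
    class_count: int = 2

    def partition(self, name: str) -> list[Tile]:
        return [t for t, s in zip(self.tiles, self.split) if s == name]


def crop_tiles(scene: SceneBundle | tuple[np.ndarray, np.ndarray],
               tile_size: int) -> list[Tile]:
    """Non-overlapping reading-order grid crop of image and mask together."""
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    if isinstance(scene, SceneBundle):
        image, mask = scene.image, scene.instance_mask
    else:
        image, mask = scene
    h, w = mask.shape
    n_r, n_c = h // tile_size, w // tile_size
    if n_r == 0 or n_c == 0:
        warnings.warn(
            f"scene {(h, w)} is smaller than one {tile_size}-px tile; no tiles produced",
            stacklevel=2,
        )
        return []
    tiles = []
    for i in range(n_r):
        for j in range(n_c):
            r, c = i * tile_size, j * tile_size
            tiles.append(
                Tile(
                    image=np.ascontiguousarray(image[r : r + tile_size, c : c + tile_size]),
                    mask=np.ascontiguousarray(mask[r : r + tile_size, c : c + tile_size]),
                    origin=(r, c),
                )
            )
    return tiles


def _apply_op(arr: np.ndarray, tag: str) -> np.ndarray:
    if tag == "identity":
        return arr.copy()
    if tag == "hflip":
        return np.ascontiguousarray(arr[:, ::-1])
    if tag == "vflip":
        return np.ascontiguousarray(arr[::-1])
    if tag == "transpose":
        return np.ascontiguousarray(arr.swapaxes(0, 1))
    raise ValueError(f"unknown augmentation {tag!r}")


def augment_tiles(tiles: Sequence[Tile], enabled: bool = True) -> list[Tile]:
    """Expand each tile into its 4 axis-symmetry views (image and mask alike)."""
    if not enabled:
        return list(tiles)
    out = []
    for t in tiles:
        h, w = t.mask.shape
        if h != w:
            raise ValueError(f"transpose augmentation requires square tiles, got {(h, w)}")
        for tag in AUGMENTATION_TAGS:
            out.append(
                Tile(
                    image=_apply_op(t.image, tag),
                    mask=_apply_op(t.mask, tag),
                    origin=t.origin,
                    augmentation_tag=tag,
                )
            )
    return out


def split_dataset(tiles: Sequence[Tile], ratios: tuple[float, float, float] = (8, 1, 1),
                  seed: int = 0, augment_train: bool = False,
                  class_count: int = 2) -> TileSet:
    """Shuffle tiles and assign train/test/validation by the given ratios.

    Counts follow the exact ratio where possible (floor per partition,
    remainder handed out train, then test, then validation). When
    ``augment_train`` is set, only the training partition is expanded.
    """
    if any(r <= 0 for r in ratios):
        raise ValueError("split ratios must be positive")
    n = len(tiles)
    if n < 3:
        raise ValueError(f"need at least 3 tiles to form 3 partitions, got {n}")
    total = sum(ratios)
    counts = [int(n * r / total) for r in ratios]
    for k in range(n - sum(counts)):
        counts[k % 3] += 1
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    names = ("train", "test", "validation")
    assign = {}
    pos = 0
    for name, cnt in zip(names, counts):
        for idx in order[pos : pos + cnt]:
            assign[int(idx)] = name
        pos += cnt

    out_tiles: list[Tile] = []
    out_split: list[str] = []
    for i, t in enumerate(tiles):
        s = assign[i]
        if s == "train" and augment_train:
            for aug in augment_tiles([t]):
                out_tiles.append(aug)
                out_split.append(s)
        else:
            out_tiles.append(t)
            out_split.append(s)
    return TileSet(tiles=out_tiles, split=out_split, class_count=class_count)


def to_semantic(instance_mask: np.ndarray) -> np.ndarray:
    """Collapse an instance mask to a background/plant semantic mask."""
    return (instance_mask > 0).astype(np.int32)


def one_hot_encode(mask: np.ndarray, class_count: int) -> np.ndarray:
    """(h, w) integer mask -> (h, w, class_count) one-hot layers.

    Every pixel contributes a single 1, so the layers sum to one
    everywhere.
    """
    mask = np.asarray(mask)
    bad = (mask < 0) | (mask >= class_count)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"mask value {mask[r, c]} at pixel ({r}, {c}) outside [0, {class_count})"
        )
    return np.eye(class_count, dtype=np.float32)[mask]
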