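"""Shared fixtures: synthetic scenes and a desk-scale trained segmenter.

Training fixtures are session-scoped so the (CPU-minutes) cost of
fitting the UNet is paid once and shared by every test that inspects a
trained model.
"""

from __future__ import annotations

import numpy as np
import pytest

from uavpheno.scene import SceneConfig, generate_scene
from uavpheno.segmentation import UNetConfig, train_unet
from uavpheno.tiling import Tile, crop_tiles, split_dataset


@pytest.fixture(scope="session")
def small_scene():
    """3 rows x 4 plants on a 384 px field; the 'default' desk scene."""
    cfg = SceneConfig(
        field_size=(384, 384), n_rows=3, plants_per_row=4,
        row_spacing_px=100, within_row_spacing_px=88, seed=7,
    )
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def seg_scene():
    """Larger field yielding 36 tiles of 96 px for segmentation training."""
    cfg = SceneConfig(
        field_size=(576, 576), n_rows=5, plants_per_row=6,
        row_spacing_px=100, within_row_spacing_px=90, seed=11,
    )
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def desk_seg(seg_scene):
    """RGB tileset (augmented training partition) and a UNet trained on it.

    36 base tiles of 96 px, 6 epochs: enough for the high-contrast
    synthetic task while keeping the suite CPU-friendly.
    """
    tiles = crop_tiles(seg_scene, 96)
    tiles_rgb = [Tile(image=t.image[:, :, :3], mask=t.mask, origin=t.origin)
                 for t in tiles]
    tileset = split_dataset(tiles_rgb, ratios=(8, 1, 1), seed=1, augment_train=True)
    cfg = UNetConfig(in_channels=3, base_filters=8, batch_size=4,
                     learning_rate=2e-3, epochs=6, seed=0)
    handle = train_unet(tileset, cfg)
    return tileset, handle
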