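"""Synthetic scene generator: layout, spectra, truth table, degradation, I/O."""

import numpy as np
import pandas as pd
import pytest

from uavpheno.scene import (
    SceneConfig,
    _ellipse_pixels,
    degrade_image,
    generate_scene,
    read_bundle,
    write_bundle,
)
from uavpheno.traits import fit_spad_mlr


def _config(**kw):
    base = dict(field_size=(384, 384), n_rows=3, plants_per_row=4,
                row_spacing_px=100, within_row_spacing_px=88, seed=7)
    base.update(kw)
    return SceneConfig(**base)


class TestGenerateScene:
    def test_label_count_matches_layout(self, small_scene):
        labels = set(np.unique(small_scene.instance_mask)) - {0}
        assert len(labels) == 12
        assert len(small_scene.truth) == 12
        assert labels == set(small_scene.truth["plant_id"])

    def test_deterministic_given_seed(self):
        a = generate_scene(_config())
        b = generate_scene(_config())
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.instance_mask, b.instance_mask)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_different_seed_differs(self):
        a = generate_scene(_config())
        b = generate_scene(_config(seed=8))
        assert not np.array_equal(a.image, b.image)

    def test_truth_extents_match_mask_times_gsd(self, small_scene):
        """Closing the loop with the ground-scale model: the stored meter
        extents are exactly the rasterized pixel extents times the GSD."""
        for _, row in small_scene.truth.iterrows():
            rr, cc = np.nonzero(small_scene.instance_mask == row["plant_id"])
            ext = sorted([rr.max() - rr.min() + 1, cc.max() - cc.min() + 1])
            assert row["width_px"] == ext[0]
            assert row["length_px"] == ext[1]
            assert row["true_length_m"] == pytest.approx(
                ext[1] * small_scene.gsd_m, rel=1e-12)
            assert row["true_length_m"] >= row["true_width_m"]

    def test_vegetation_nir_contrast(self, small_scene):
        """Plant pixels sit above soil pixels in NIR - R nearly everywhere."""
        nir_r = small_scene.image[:, :, 4] - small_scene.image[:, :, 0]
        plant = nir_r[small_scene.instance_mask > 0]
        soil = nir_r[small_scene.instance_mask == 0]
        threshold = np.quantile(soil, 0.99)
        assert np.mean(plant > threshold) >= 0.99

    def test_noiseless_spad_is_exactly_linear_in_channel_means(self):
        """Generator and MLR are mutually consistent: with no SPAD noise the
        generating coefficients are recovered to numerical precision."""
        scene = generate_scene(_config(spad_noise_sd=0.0, seed=3))
        feats = scene.truth[["mean_R", "mean_G", "mean_B"]].to_numpy()
        model = fit_spad_mlr(feats, scene.truth["true_spad"].to_numpy(), mode="RGB")
        b0, bR, bG, bB = SceneConfig().spad_coeffs
        assert model.intercept == pytest.approx(b0, abs=1e-8)
        assert model.coefficients == pytest.approx([bR, bG, bB], abs=1e-8)

    def test_infeasible_layout_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            generate_scene(_config(field_size=(120, 120)))

    def test_row_separability_enforced(self):
        with pytest.raises(ValueError, match="separable"):
            _config(row_spacing_px=40)


class TestEllipseRasterization:
    def test_axis_aligned_bbox_vs_brute_force(self):
        """(a, b) = (20, 30) semi-axes centered on an integer pixel span an
        inclusive bounding box of 41 x 61 px; cross-check every pixel against
        the quadratic-form membership test evaluated point by point."""
        shape = (200, 200)
        center, axes = (100.0, 100.0), (30.0, 20.0)  # a along columns
        rr, cc = _ellipse_pixels(center, axes, 0.0, shape)
        brute = [
            (r, c)
            for r in range(shape[0])
            for c in range(shape[1])
            if ((c - center[1]) / axes[0]) ** 2 + ((r - center[0]) / axes[1]) ** 2 <= 1
        ]
        assert set(zip(rr.tolist(), cc.tolist())) == set(brute)
        assert rr.max() - rr.min() + 1 == 41
        assert cc.max() - cc.min() + 1 == 61

    def test_rotation_by_90_degrees_swaps_extents(self):
        rr0, cc0 = _ellipse_pixels((60.0, 60.0), (25.0, 10.0), 0.0, (120, 120))
        rr1, cc1 = _ellipse_pixels((60.0, 60.0), (25.0, 10.0), np.pi / 2, (120, 120))
        assert rr0.max() - rr0.min() == cc1.max() - cc1.min()
        assert cc0.max() - cc0.min() == rr1.max() - rr1.min()


class TestDegradeImage:
    def test_shape_contract(self):
        img = np.zeros((608, 608, 3), dtype=np.float32)
        assert degrade_image(img, 4).shape == (152, 152, 3)

    def test_constant_preserved_without_noise(self):
        img = np.full((64, 64), 0.4, dtype=np.float32)
        out = degrade_image(img, 4, blur_sd=1.5, noise_sd=0.0)
        assert out.shape == (16, 16)
        assert np.allclose(out, 0.4, atol=1e-6)

    def test_block_means_exact(self):
        """4x4-block checkerboard, no blur/noise: output equals block means."""
        blocks = np.arange(16, dtype=np.float64).reshape(4, 4) / 16.0
        img = np.kron(blocks, np.ones((4, 4)))
        out = degrade_image(img, 4, blur_sd=0.0, noise_sd=0.0)
        assert np.allclose(out, blocks, atol=1e-7)

    def test_nondivisible_dimensions_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            degrade_image(np.zeros((50, 48)), 4)

    def test_deterministic_noise(self):
        img = np.full((32, 32), 0.5, dtype=np.float32)
        a = degrade_image(img, 2, noise_sd=0.05, seed=9)
        b = degrade_image(img, 2, noise_sd=0.05, seed=9)
        assert np.array_equal(a, b)


class TestBundleIO:
    def test_round_trip(self, small_scene, tmp_path):
        write_bundle(small_scene, tmp_path / "scene")
        back = read_bundle(tmp_path / "scene")
        assert np.array_equal(back.image, small_scene.image)
        assert np.array_equal(back.instance_mask, small_scene.instance_mask)
        assert back.gsd_m == pytest.approx(small_scene.gsd_m, rel=1e-12)
        pd.testing.assert_frame_equal(
            back.truth.reset_index(drop=True),
            small_scene.truth.reset_index(drop=True),
            check_dtype=False, check_exact=False, rtol=1e-12,
        )

    def test_truth_rows_equal_mask_labels(self, small_scene, tmp_path):
        write_bundle(small_scene, tmp_path / "scene")
        back = read_bundle(tmp_path / "scene")
        labels = set(np.unique(back.instance_mask)) - {0}
        assert len(back.truth) == len(labels)

    def test_duplicated_plant_id_rejected(self, small_scene, tmp_path):
        write_bundle(small_scene, tmp_path / "scene")
        csv = tmp_path / "scene" / "truth.csv"
        df = pd.read_csv(csv)
        df.loc[1, "plant_id"] = df.loc[0, "plant_id"]
        df.to_csv(csv, index=False)
        with pytest.raises(ValueError, match="duplicated plant_id"):
            read_bundle(tmp_path / "scene")
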