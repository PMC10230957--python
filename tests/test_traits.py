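"""Trait extraction: regions, physical sizes, SPAD regression, statistics."""

import numpy as np
import pandas as pd
import pytest

from uavpheno.camera import GroundScale
from uavpheno.scene import _ellipse_pixels
from uavpheno.traits import (
    EvalReport,
    TraitRecord,
    evaluate_predictions,
    extract_region_features,
    fit_spad_mlr,
    label_regions,
    match_to_truth,
    predict_spad,
    region_to_physical,
)


class TestLabelRegions:
    def test_two_disjoint_squares(self):
        mask = np.zeros((20, 20), dtype=int)
        mask[2:7, 2:7] = 1
        mask[12:17, 12:17] = 1
        regions = label_regions(mask)
        assert len(regions) == 2
        assert all(r.area_px == 25 for r in regions)
        assert [r.region_id for r in regions] == [1, 2]

    def test_diagonal_touch_is_one_region(self):
        mask = np.zeros((4, 4), dtype=int)
        mask[1, 1] = mask[2, 2] = 1
        assert len(label_regions(mask)) == 1

    def test_min_area_filters_specks(self):
        mask = np.zeros((30, 30), dtype=int)
        mask[2:12, 2:12] = 1          # 100 px blob
        mask[20, 20:23] = 1           # 3 px speck
        regions = label_regions(mask, min_area_px=10)
        assert len(regions) == 1
        assert regions[0].area_px == 100

    def test_empty_mask_gives_empty_list(self):
        assert label_regions(np.zeros((5, 5), dtype=int)) == []

    def test_reading_order_numbering(self):
        mask = np.zeros((20, 40), dtype=int)
        mask[10:14, 30:34] = 1
        mask[2:6, 2:6] = 1
        regions = label_regions(mask)
        assert regions[0].bbox[:2] == (2, 2)
        assert regions[1].bbox[:2] == (10, 30)


class TestRegionFeatures:
    def test_rectangle_extents(self):
        mask = np.zeros((30, 30), dtype=int)
        mask[5:15, 5:25] = 1          # 10 rows x 20 cols
        region = label_regions(mask)[0]
        assert region.width_px == 10
        assert region.length_px == 20

    def test_constant_image_channel_means(self):
        mask = np.zeros((10, 10), dtype=int)
        mask[2:8, 2:8] = 1
        img = np.full((10, 10, 3), 0.42, dtype=np.float32)
        region = extract_region_features(label_regions(mask)[0], img)
        assert region.channel_means == pytest.approx((0.42, 0.42, 0.42), abs=1e-6)

    def test_means_exclude_background(self):
        mask = np.zeros((10, 10), dtype=int)
        mask[0:2, 0:2] = 1
        img = np.zeros((10, 10, 3), dtype=np.float32)
        img[0:2, 0:2] = 1.0           # region bright, background dark
        region = extract_region_features(label_regions(mask)[0], img)
        assert region.channel_means == pytest.approx((1.0, 1.0, 1.0))

    def test_ellipse_extents_match_rasterization_oracle(self):
        """Semi-axes (20, 30) rasterize to inclusive extents 41 x 61."""
        mask = np.zeros((200, 200), dtype=int)
        rr, cc = _ellipse_pixels((100.0, 100.0), (30.0, 20.0), 0.0, mask.shape)
        mask[rr, cc] = 1
        region = label_regions(mask)[0]
        assert region.length_px == 61
        assert region.width_px == 41


class TestRegionToPhysical:
    def test_gsd_conversion(self):
        mask = np.zeros((70, 70), dtype=int)
        rr, cc = _ellipse_pixels((34.0, 34.0), (30.0, 20.0), 0.0, mask.shape)
        mask[rr, cc] = 1
        region = label_regions(mask)[0]
        length, width = region_to_physical(region, GroundScale(gsd_m=5.2265e-3))
        assert length == pytest.approx(61 * 5.2265e-3, rel=1e-9)   # ~0.319 m
        assert width == pytest.approx(41 * 5.2265e-3, rel=1e-9)

    def test_sr_factor_quarters_lengths(self):
        mask = np.zeros((12, 12), dtype=int)
        mask[2:10, 2:10] = 1
        region = label_regions(mask)[0]
        l1, w1 = region_to_physical(region, GroundScale(gsd_m=5e-3, sr_factor=1))
        l4, w4 = region_to_physical(region, GroundScale(gsd_m=5e-3, sr_factor=4))
        assert l4 == pytest.approx(l1 / 4)
        assert w4 == pytest.approx(w1 / 4)


class TestSpadMlr:
    def _data(self, n, noise_sd, seed, coeffs=(10.0, 0.1, 0.2, 0.05)):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 1, size=(n, 3))
        b0, bR, bG, bB = coeffs
        y = b0 + x @ [bR, bG, bB] + rng.normal(0, noise_sd, n)
        return x, y

    def test_noiseless_recovery(self):
        x, y = self._data(50, 0.0, 0)
        model = fit_spad_mlr(x, y, mode="RGB")
        assert model.intercept == pytest.approx(10.0, abs=1e-8)
        assert model.coefficients == pytest.approx([0.1, 0.2, 0.05], abs=1e-8)
        pred, flags = predict_spad(model, x)
        assert pred == pytest.approx(y, abs=1e-8)
        assert not flags.any()

    def test_noisy_coefficients_within_three_stderr(self):
        x, y = self._data(200, 1.5, 42)
        model = fit_spad_mlr(x, y, mode="RGB")
        truth = np.array([10.0, 0.1, 0.2, 0.05])
        est = np.concatenate([[model.intercept], model.coefficients])
        assert np.all(np.abs(est - truth) <= 3 * model.stderr)

    def test_g_only_has_one_slope(self):
        x, y = self._data(50, 0.5, 1)
        model = fit_spad_mlr(x, y, mode="G_only")
        assert len(model.coefficients) == 1
        pred, _ = predict_spad(model, x[:, [1]])
        assert len(pred) == 50

    def test_rank_deficient_names_columns(self):
        x, y = self._data(50, 0.0, 2)
        x[:, 2] = 0.7                 # constant B column
        with pytest.raises(ValueError, match=r"collinear.*B"):
            fit_spad_mlr(x, y, mode="RGB")

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit_spad_mlr(np.ones((3, 3)) * [[0.1, 0.2, 0.3]], [1, 2, 3], mode="RGB")

    def test_prediction_is_affine(self):
        x, y = self._data(50, 0.3, 3)
        model = fit_spad_mlr(x, y, mode="RGB")
        p0, _ = predict_spad(model, np.zeros((1, 3)))
        assert p0[0] == pytest.approx(model.intercept)
        px, _ = predict_spad(model, x[:1])
        p2x, _ = predict_spad(model, 2 * x[:1])
        assert p2x[0] - p0[0] == pytest.approx(2 * (px[0] - p0[0]), rel=1e-9)

    def test_feature_column_mismatch_rejected(self):
        x, y = self._data(50, 0.3, 4)
        model = fit_spad_mlr(x, y, mode="RGB")
        with pytest.raises(ValueError):
            predict_spad(model, np.zeros((5, 2)))

    def test_no_spurious_signal_on_null_coefficient(self):
        """Data generated with bB = 0: |t| of the B slope stays below 3 in
        at least 95 of 100 seeded replicates."""
        hits = 0
        for seed in range(100):
            x, y = self._data(60, 1.0, seed, coeffs=(10.0, 0.1, 0.2, 0.0))
            model = fit_spad_mlr(x, y, mode="RGB")
            t_b = model.coefficients[2] / model.stderr[3]
            hits += abs(t_b) < 3
        assert hits >= 95

    def test_holdout_rmse_at_default_noise(self):
        """At the generator's default SPAD noise (sd 1.5) and n = 200, the
        held-out RMSE stays within the low-single-digit band expected of a
        well-posed linear SPAD model."""
        x, y = self._data(300, 1.5, 7, coeffs=(62.0, 25.0, -110.0, 15.0))
        model = fit_spad_mlr(x[:200], y[:200], mode="RGB")
        pred, _ = predict_spad(model, x[200:])
        rmse = float(np.sqrt(np.mean((pred - y[200:]) ** 2)))
        assert rmse <= 2.2


class TestEvaluatePredictions:
    def test_perfect_predictions(self):
        rep = evaluate_predictions([1, 2, 3], [1, 2, 3])
        assert (rep.r2, rep.rmspe, rep.rmse) == (1.0, 0.0, 0.0)
        assert rep.n == 3

    def test_mean_predictor_scores_zero(self):
        rep = evaluate_predictions([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert rep.r2 == 0.0

    def test_explained_variance_form_can_exceed_one(self):
        """actual (1,2,3) vs predicted (1,2,4): RMSE = sqrt(1/3) and the
        explained-variance R^2 is 5/2 — the as-defined SSR/SST ratio."""
        rep = evaluate_predictions([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert rep.rmse == pytest.approx(np.sqrt(1 / 3), rel=1e-12)
        assert rep.r2 == pytest.approx(2.5, rel=1e-12)
        rep_res = evaluate_predictions([1.0, 2.0, 3.0], [1.0, 2.0, 4.0],
                                       r2_mode="residual")
        assert rep_res.r2 == pytest.approx(0.5, rel=1e-12)

    def test_rmspe_hand_case(self):
        rep = evaluate_predictions([2.0, 4.0], [1.0, 5.0])
        assert rep.rmspe == pytest.approx(np.sqrt((0.25 + 0.0625) / 2), rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            evaluate_predictions([2.0, 2.0], [1.0, 3.0])

    def test_zero_actual_rejected_for_rmspe(self):
        with pytest.raises(ValueError, match="zero"):
            evaluate_predictions([0.0, 1.0], [0.5, 1.0])

    def test_brute_force_equivalence_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(2, 30))
            y = rng.uniform(1, 10, n)
            yhat = y + rng.normal(0, 1, n)
            rep = evaluate_predictions(y, yhat)
            ybar = sum(y) / n
            sst = sum((v - ybar) ** 2 for v in y)
            r2 = sum((v - ybar) ** 2 for v in yhat) / sst
            rmspe = (sum(((a - p) / a) ** 2 for a, p in zip(y, yhat)) / n) ** 0.5
            rmse = (sum((a - p) ** 2 for a, p in zip(y, yhat)) / n) ** 0.5
            assert rep.r2 == pytest.approx(r2, rel=1e-12)
            assert rep.rmspe == pytest.approx(rmspe, rel=1e-12)
            assert rep.rmse == pytest.approx(rmse, rel=1e-12)


def _truth_frame(centers):
    return pd.DataFrame({
        "plant_id": range(1, len(centers) + 1),
        "center_row_px": [c[0] for c in centers],
        "center_col_px": [c[1] for c in centers],
        "true_length_m": 0.3,
        "true_width_m": 0.2,
        "true_spad": 40.0,
    })


def _record(rid, centroid):
    return TraitRecord(region_id=rid, pred_length_m=0.3, pred_width_m=0.2,
                       centroid=centroid)


class TestMatchToTruth:
    def test_identical_centroids_match_perfectly(self):
        truth = _truth_frame([(10, 10), (50, 50), (90, 10)])
        records = [_record(i + 1, c) for i, c in enumerate([(10, 10), (50, 50), (90, 10)])]
        matched, un_r, un_t = match_to_truth(records, truth, max_dist_px=5)
        assert un_r == [] and un_t == []
        assert [r.matched_truth_id for r in matched] == [1, 2, 3]
        assert matched[0].true_spad == 40.0

    def test_far_prediction_unmatched(self):
        truth = _truth_frame([(10, 10)])
        records = [_record(1, (10.0, 11.0)), _record(2, (200.0, 200.0))]
        matched, un_r, un_t = match_to_truth(records, truth, max_dist_px=20)
        assert un_r == [2] and un_t == []
        assert matched[0].matched_truth_id == 1

    def test_equidistant_tie_goes_to_reading_order(self):
        truth = _truth_frame([(10, 10)])
        records = [_record(1, (10.0, 8.0)), _record(2, (10.0, 12.0))]
        matched, un_r, un_t = match_to_truth(records, truth, max_dist_px=20)
        assert matched[0].matched_truth_id == 1
        assert un_r == [2]
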