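"""Per-plant trait extraction from segmentation masks.

A semantic plant/background mask is split into plant instances by
8-connected components; each region yields pixel extents (orientation-
free: length is the larger bounding-box side, width the smaller),
channel means over region pixels after background removal, and physical
sizes via the ground sampling distance. Leaf chlorophyll (SPAD) is
predicted by a multiple linear regression on the visible channel means
(G only, or R+G+B).

Prediction quality is summarized by three statistics:

    R^2   = sum((yhat_i - ybar)^2) / sum((y_i - ybar)^2)
    RMSPE = sqrt( (1/n) * sum(((y_i - yhat_i) / y_i)^2) )
    RMSE  = sqrt( (1/n) * sum((y_i - yhat_i)^2) )

The R^2 here is the explained-variance ratio (SSR/SST), which is *not*
the residual-based 1 - SSE/SST and can exceed 1 for a biased predictor;
``evaluate_predictions`` implements this form by default and offers the
residual form behind ``r2_mode="residual"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from skimage import measure

from .camera import GroundScale, px_to_length

__all__ = [
    "PlantRegion",
    "MLRModel",
    "EvalReport",
    "TraitRecord",
    "label_regions",
    "extract_region_features",
    "region_to_physical",
    "fit_spad_mlr",
    "predict_spad",
    "evaluate_predictions",
    "match_to_truth",
]


@dataclass
class PlantRegion:
    """One segmented plant instance.

    ``bbox`` is 0-based, half-open (min_row, min_col, max_row, max_col);
    pixel extents are bbox side lengths, reported orientation-free as
    length >= width.
    """

    region_id: int
    bbox: tuple[int, int, int, int]
    length_px: int
    width_px: int
    area_px: int
    centroid: tuple[float, float]
    channel_means: Optional[tuple[float, ...]] = None
    coords: Optional[np.ndarray] = None  # (n, 2) row/col of region pixels


@dataclass(frozen=True)
class MLRModel:
    """Ordinary-least-squares SPAD model on visible channel means."""

    mode: Literal["G_only", "RGB"]
    intercept: float
    coefficients: np.ndarray
    stderr: np.ndarray          # standard errors: (intercept, *slopes)
    fit_n: int

    def __post_init__(self) -> None:
        expected = 1 if self.mode == "G_only" else 3
        if len(self.coefficients) != expected:
            raise ValueError(
                f"mode {self.mode!r} requires {expected} coefficients, "
                f"got {len(self.coefficients)}"
            )


@dataclass(frozen=True)
class EvalReport:
    r2: float
    rmspe: float
    rmse: float
    n: int


@dataclass
class TraitRecord:
    region_id: int
    pred_length_m: float
    pred_width_m: float
    pred_spad: Optional[float] = None
    spad_out_of_range: bool = False
    centroid: Optional[tuple[float, float]] = None
    matched_truth_id: Optional[int] = None
    true_length_m: Optional[float] = None
    true_width_m: Optional[float] = None
    true_spad: Optional[float] = None


def label_regions(mask: np.ndarray, min_area_px: int = 0) -> list[PlantRegion]:
    """8-connected components of a plant/background mask, reading order.

    Components smaller than ``min_area_px`` are dropped (mask specks from
    imperfect segmentation); survivors are renumbered 1..n by the reading
    order of their top-left bounding-box corner.
    """
    lab = measure.label(np.asarray(mask) > 0, connectivity=2)
    regions = []
    for rp in measure.regionprops(lab):
        if rp.area < min_area_px:
            continue
        minr, minc, maxr, maxc = rp.bbox
        ext_r, ext_c = maxr - minr, maxc - minc
        regions.append(
            PlantRegion(
                region_id=-1,
                bbox=(minr, minc, maxr, maxc),
                length_px=max(ext_r, ext_c),
                width_px=min(ext_r, ext_c),
                area_px=int(rp.area),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                coords=rp.coords.copy(),
            )
        )
    regions.sort(key=lambda r: (r.bbox[0], r.bbox[1]))
    for i, r in enumerate(regions, start=1):
        r.region_id = i
    return regions


def extract_region_features(region: PlantRegion, rgb_image: np.ndarray) -> PlantRegion:
    """Fill in channel means over region pixels only (background removed)."""
    if region.coords is None or len(region.coords) == 0:
        raise ValueError(f"region {region.region_id} has no pixels")
    img = rgb_image
    if img.ndim == 2:
        img = img[:, :, None]
    rr, cc = region.coords[:, 0], region.coords[:, 1]
    if rr.max() >= img.shape[0] or cc.max() >= img.shape[1]:
        raise ValueError("region pixels fall outside the image bounds")
    region.channel_means = tuple(float(img[rr, cc, b].mean()) for b in range(img.shape[2]))
    return region


def region_to_physical(region: PlantRegion, scale: GroundScale) -> tuple[float, float]:
    """(length_m, width_m) of one region via the ground scale."""
    return (
        px_to_length(region.length_px, scale),
        px_to_length(region.width_px, scale),
    )


def _design(features: np.ndarray, mode: str) -> np.ndarray:
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[:, None]
    if mode == "G_only":
        if features.shape[1] == 3:
            features = features[:, [1]]
        elif features.shape[1] != 1:
            raise ValueError(
                f"G_only mode expects 1 (G) or 3 (R,G,B) feature columns, "
                f"got {features.shape[1]}"
            )
    elif mode == "RGB":
        if features.shape[1] != 3:
            raise ValueError(f"RGB mode expects 3 feature columns, got {features.shape[1]}")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return features


def fit_spad_mlr(features: np.ndarray, spad: np.ndarray,
                 mode: Literal["G_only", "RGB"] = "RGB") -> MLRModel:
    """OLS with intercept of SPAD on channel means.

    ``features`` columns are (R, G, B) for RGB mode (a 3-column input in
    G_only mode uses its G column), and a single G column otherwise.
    """
    x = _design(features, mode)
    y = np.asarray(spad, dtype=float)
    n, p = x.shape
    if len(y) != n:
        raise ValueError("features and spad lengths differ")
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} samples to fit {p} slopes, got {n}")
    design = sm.add_constant(x, has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        names = ["R", "G", "B"] if mode == "RGB" else ["G"]
        const = [names[j] for j in range(p) if np.ptp(x[:, j]) == 0]
        detail = f" (constant columns: {const})" if const else ""
        raise ValueError(f"design matrix is rank deficient; collinear predictors{detail}")
    res = sm.OLS(y, design).fit()
    return MLRModel(
        mode=mode,
        intercept=float(res.params[0]),
        coefficients=np.asarray(res.params[1:], dtype=float),
        stderr=np.asarray(res.bse, dtype=float),
        fit_n=n,
    )


def predict_spad(model: MLRModel, features: np.ndarray,
                 spad_range: tuple[float, float] = (0.0, 99.0)):
    """Linear SPAD prediction; values outside ``spad_range`` are flagged,
    never clipped. Returns (predictions, out_of_range_flags)."""
    x = _design(features, model.mode)
    if x.shape[1] != len(model.coefficients):
        raise ValueError(
            f"feature columns ({x.shape[1]}) do not match model mode {model.mode!r}"
        )
    pred = model.intercept + x @ model.coefficients
    flags = (pred < spad_range[0]) | (pred > spad_range[1])
    return pred, flags


def evaluate_predictions(actual: Sequence[float], predicted: Sequence[float],
                         r2_mode: Literal["explained", "residual"] = "explained",
                         ) -> EvalReport:
    """R^2 / RMSPE / RMSE of predictions against reference measurements.

    The default R^2 is the explained-variance ratio SSR/SST (see module
    docstring); ``r2_mode="residual"`` gives the usual 1 - SSE/SST.
    """
    y = np.asarray(actual, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("actual and predicted must be 1-D of equal length")
    n = len(y)
    if n < 2:
        raise ValueError(f"need n >= 2 observations, got {n}")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("R^2 undefined: actual values have zero variance")
    if np.any(y == 0.0):
        raise ValueError("RMSPE undefined: actual values contain zeros")
    if r2_mode == "explained":
        r2 = float(np.sum((yhat - y.mean()) ** 2)) / sst
    elif r2_mode == "residual":
        r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / sst
    else:
        raise ValueError(f"unknown r2_mode {r2_mode!r}")
    rmspe = float(np.sqrt(np.mean(((y - yhat) / y) ** 2)))
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    return EvalReport(r2=r2, rmspe=rmspe, rmse=rmse, n=n)


def match_to_truth(records: Sequence[TraitRecord], truth: pd.DataFrame,
                   max_dist_px: float = 20.0,
                   ) -> tuple[list[TraitRecord], list[int], list[int]]:
    """Greedy mutual-nearest centroid matching of predictions to truth.

    Candidate pairs within ``max_dist_px`` are taken nearest first; ties
    break toward the record earlier in reading order, then the lower
    plant_id. Returns (records, unmatched_record_ids, unmatched_truth_ids);
    matched records carry the truth values.
    """
    t_ids = truth["plant_id"].to_numpy()
    t_pos = truth[["center_row_px", "center_col_px"]].to_numpy(dtype=float)
    pairs = []
    for i, rec in enumerate(records):
        if rec.centroid is None:
            raise ValueError(f"record {rec.region_id} has no centroid")
        d = np.hypot(t_pos[:, 0] - rec.centroid[0], t_pos[:, 1] - rec.centroid[1])
        for j in np.nonzero(d <= max_dist_px)[0]:
            pairs.append((float(d[j]), i, int(j)))
    pairs.sort(key=lambda p: (p[0], p[1], p[2]))
    used_r, used_t = set(), set()
    for dist, i, j in pairs:
        if i in used_r or j in used_t:
            continue
        used_r.add(i)
        used_t.add(j)
        rec = records[i]
        rec.matched_truth_id = int(t_ids[j])
        row = truth.iloc[j]
        rec.true_length_m = float(row["true_length_m"])
        rec.true_width_m = float(row["true_width_m"])
        rec.true_spad = float(row["true_spad"])
    unmatched_records = [r.region_id for k, r in enumerate(records) if k not in used_r]
    unmatched_truths = [int(t_ids[j]) for j in range(len(t_ids)) if j not in used_t]
    return list(records), unmatched_records, unmatched_truths
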