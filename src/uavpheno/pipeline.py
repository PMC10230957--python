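"""End-to-end experiment: scene -> tiles -> model variants -> traits.

Three model variants mirror the study design: ``multispectral`` (5-band
input), ``rgb`` (visible bands), and ``rgb_sr`` (visible bands whose
resolution is first enhanced 4x by the SRGAN stage, with masks upscaled
to match and physical sizes recovered through the ``sr_factor`` of the
ground scale). All variants share the same scene, tiling and split, so
their comparison is paired: only the input bands and the enhancement
differ.

Every stage writes its artifacts under ``output_dir`` and can be resumed
(a stage whose artifacts exist is loaded, not recomputed). All
randomness fans out from the single experiment seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__
from .camera import CameraModel, GroundScale, compute_gsd
from .scene import SceneBundle, SceneConfig, degrade_image, generate_scene, read_bundle, write_bundle
from .segmentation import SegModelHandle, UNetConfig, pixel_accuracy, predict_mask, train_unet
from .sr import SRGANConfig, SRModelHandle, enhance_image, train_srgan
from .tiling import Tile, TileSet, crop_tiles, split_dataset
from .traits import (
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

__all__ = ["ExperimentConfig", "ComparisonReport", "ConfigError", "run_experiment",
           "compare_variants", "default_config"]

log = logging.getLogger("uavpheno")

VARIANTS = ("multispectral", "rgb", "rgb_sr")


class ConfigError(ValueError):
    """Raised before any computation when the experiment config is invalid."""


@dataclass(frozen=True)
class DatasetConfig:
    tile_size: int = 96
    ratios: tuple[float, float, float] = (8.0, 1.0, 1.0)
    augment: bool = True


@dataclass(frozen=True)
class TraitsConfig:
    min_area_px: int = 30
    max_match_dist_px: float = 25.0
    mlr_mode: str = "RGB"
    spad_range: tuple[float, float] = (0.0, 99.0)


@dataclass(frozen=True)
class ExperimentConfig:
    camera: CameraModel
    scene: SceneConfig
    dataset: DatasetConfig
    srgan: SRGANConfig
    unet: UNetConfig
    traits: TraitsConfig
    variants: tuple[str, ...] = VARIANTS
    output_dir: str = "runs/experiment"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.variants:
            raise ConfigError("at least one variant must be requested")
        unknown = set(self.variants) - set(VARIANTS)
        if unknown:
            raise ConfigError(f"unknown variants {sorted(unknown)}; choose from {VARIANTS}")

    @classmethod
    def from_dict(cls, raw: Mapping, seed: Optional[int] = None,
                  output_dir: Optional[str] = None) -> "ExperimentConfig":
        """Build from a nested config mapping (the parsed YAML file).

        Required blocks: camera, scene, dataset, unet, traits; ``srgan``
        is required only when the rgb_sr variant is requested.
        """
        variants = tuple(raw.get("variants", VARIANTS))
        required = ["camera", "scene", "dataset", "unet", "traits"]
        if "rgb_sr" in variants:
            required.append("srgan")
        for block in required:
            if block not in raw:
                raise ConfigError(f"config is missing the required '{block}:' block")
        try:
            camera = CameraModel.from_config(raw["camera"])
            scene = SceneConfig(**_tupled(raw["scene"]))
            dataset = DatasetConfig(**_tupled(raw["dataset"]))
            srgan = SRGANConfig(**raw.get("srgan", {}))
            unet = UNetConfig(**raw["unet"])
            traits = TraitsConfig(**_tupled(raw["traits"]))
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc
        return cls(
            camera=camera, scene=scene, dataset=dataset, srgan=srgan, unet=unet,
            traits=traits, variants=variants,
            output_dir=output_dir or raw.get("output_dir", "runs/experiment"),
            seed=seed if seed is not None else int(raw.get("seed", 0)),
        )


def _tupled(block: Mapping) -> dict:
    """YAML lists -> tuples so frozen dataclass fields compare/validate cleanly."""
    return {k: tuple(v) if isinstance(v, list) else v for k, v in block.items()}


def default_config() -> dict:
    """Desk-scale defaults as a plain nested dict (YAML-serializable)."""
    return {
        "camera": {},
        "scene": {
            "field_size": [576, 576], "n_rows": 5, "plants_per_row": 6,
            "row_spacing_px": 100, "within_row_spacing_px": 90, "seed": 0,
        },
        "dataset": {"tile_size": 96, "ratios": [8, 1, 1], "augment": True},
        "srgan": {"epochs": 25, "perceptual_source": "pixel_mse"},
        "unet": {"base_filters": 8, "batch_size": 4, "learning_rate": 2e-3, "epochs": 6},
        "traits": {},
        "variants": ["multispectral", "rgb", "rgb_sr"],
        "output_dir": "runs/experiment",
        "seed": 0,
    }


@dataclass
class ComparisonReport:
    """Per-variant segmentation accuracy and per-trait evaluation."""

    seg_accuracy: dict[str, float]
    evals: dict[tuple[str, str], EvalReport]
    metadata: dict

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"variant": v, "trait": t, "r2": e.r2, "rmspe": e.rmspe,
             "rmse": e.rmse, "n": e.n}
            for (v, t), e in sorted(self.evals.items())
        ]
        return pd.DataFrame(rows, columns=["variant", "trait", "r2", "rmspe", "rmse", "n"])


# --------------------------------------------------------------------------
# stages


def _stage_scene(cfg: ExperimentConfig, out: Path, resume: bool) -> SceneBundle:
    path = out / "scene"
    if resume and (path / "truth.csv").exists():
        log.info("stage scene: resuming from %s", path)
        return read_bundle(path)
    scene_cfg = dataclasses.replace(
        cfg.scene, gsd_m=compute_gsd(cfg.camera), seed=cfg.scene.seed + cfg.seed
    )
    bundle = generate_scene(scene_cfg)
    write_bundle(bundle, path)
    log.info("stage scene: %d plants, field %s", len(bundle.truth), bundle.image.shape[:2])
    return bundle


def _stage_tiles(cfg: ExperimentConfig, bundle: SceneBundle, out: Path) -> TileSet:
    tiles = crop_tiles(bundle, cfg.dataset.tile_size)
    if not tiles:
        raise ConfigError("scene is smaller than one tile; enlarge the field")
    split_seed = int(np.random.default_rng(cfg.seed).integers(2**31))
    tileset = split_dataset(tiles, ratios=cfg.dataset.ratios, seed=split_seed,
                            augment_train=cfg.dataset.augment)
    index = pd.DataFrame(
        [
            {"tile_id": i, "origin_row": t.origin[0], "origin_col": t.origin[1],
             "split": s, "augmentation_tag": t.augmentation_tag}
            for i, (t, s) in enumerate(zip(tileset.tiles, tileset.split))
        ]
    )
    index.to_csv(out / "tiles_index.csv", index=False)
    log.info("stage tiles: %d tiles (%d train / %d test / %d validation)",
             len(tileset.tiles), len(tileset.partition("train")),
             len(tileset.partition("test")), len(tileset.partition("validation")))
    return tileset


def _select_bands(tileset: TileSet, bands: slice) -> TileSet:
    tiles = [Tile(image=t.image[:, :, bands], mask=t.mask, origin=t.origin,
                  augmentation_tag=t.augmentation_tag) for t in tileset.tiles]
    return TileSet(tiles=tiles, split=list(tileset.split), class_count=tileset.class_count)


def _stage_sr(cfg: ExperimentConfig, tileset: TileSet, out: Path,
              resume: bool) -> SRModelHandle:
    path = out / "sr_model.npz"
    if resume and path.exists():
        log.info("stage train-sr: resuming from %s", path)
        return SRModelHandle.load(path)
    root = np.random.default_rng(cfg.seed + 1)
    sr_cfg = dataclasses.replace(cfg.srgan, seed=int(root.integers(2**31)))
    f = sr_cfg.upscale_factor
    pairs = []
    for i, t in enumerate(tileset.partition("train")):
        hi = t.image[:, :, :3]
        lo = degrade_image(hi, f, blur_sd=1.0, noise_sd=0.005,
                           seed=int(root.integers(2**31)))
        pairs.append((lo, hi))
    handle = train_srgan(pairs, sr_cfg)
    handle.save(path)
    pd.DataFrame({"epoch": range(1, sr_cfg.epochs + 1),
                  "g_loss": handle.history["g_loss"],
                  "d_loss": handle.history["d_loss"]}).to_csv(
        out / "sr_history.csv", index=False)
    log.info("stage train-sr: %d pairs, %d epochs, final g_loss %.4g",
             len(pairs), sr_cfg.epochs, handle.history["g_loss"][-1])
    return handle


def _enhance_tileset(tileset: TileSet, handle: SRModelHandle) -> TileSet:
    """SR-enhance the RGB bands of every tile; masks upscale by nearest."""
    f = handle.config.upscale_factor
    tiles = []
    for t in tileset.tiles:
        img = enhance_image(t.image[:, :, :3], handle)
        mask = t.mask.repeat(f, axis=0).repeat(f, axis=1)
        tiles.append(Tile(image=img.astype(np.float32), mask=mask,
                          origin=(t.origin[0] * f, t.origin[1] * f),
                          augmentation_tag=t.augmentation_tag))
    return TileSet(tiles=tiles, split=list(tileset.split), class_count=tileset.class_count)


def _stage_segmentation(cfg: ExperimentConfig, variant: str, tileset: TileSet,
                        out: Path, resume: bool) -> SegModelHandle:
    path = out / f"seg_{variant}.npz"
    if resume and path.exists():
        log.info("stage train-seg[%s]: resuming from %s", variant, path)
        return SegModelHandle.load(path)
    in_channels = 5 if variant == "multispectral" else 3
    seed = int(np.random.default_rng((cfg.seed, VARIANTS.index(variant) + 2)).integers(2**31))
    unet_cfg = dataclasses.replace(cfg.unet, in_channels=in_channels, seed=seed)
    handle = train_unet(tileset, unet_cfg)
    handle.save(path)
    hist = handle.history
    pd.DataFrame({"epoch": range(1, unet_cfg.epochs + 1), **hist}).to_csv(
        out / f"seg_history_{variant}.csv", index=False)
    log.info("stage train-seg[%s]: final val accuracy %.4f", variant,
             hist["val_accuracy"][-1])
    return handle


def _assemble_mask(handle: SegModelHandle, tileset: TileSet) -> np.ndarray:
    """Predict every base tile and reassemble the scene-level mask."""
    base = [(t, s) for t, s in zip(tileset.tiles, tileset.split)
            if t.augmentation_tag == "identity"]
    ts = base[0][0].mask.shape[0]
    max_r = max(t.origin[0] for t, _ in base) + ts
    max_c = max(t.origin[1] for t, _ in base) + ts
    canvas = np.zeros((max_r, max_c), dtype=np.int32)
    for t, _ in base:
        canvas[t.origin[0]: t.origin[0] + ts,
               t.origin[1]: t.origin[1] + ts] = predict_mask(handle, t.image)
    return canvas


def _assemble_image(tileset: TileSet) -> np.ndarray:
    base = [t for t, s in zip(tileset.tiles, tileset.split)
            if t.augmentation_tag == "identity"]
    ts = base[0].mask.shape[0]
    max_r = max(t.origin[0] for t in base) + ts
    max_c = max(t.origin[1] for t in base) + ts
    canvas = np.zeros((max_r, max_c, base[0].image.shape[2]), dtype=np.float32)
    for t in base:
        canvas[t.origin[0]: t.origin[0] + ts, t.origin[1]: t.origin[1] + ts] = t.image
    return canvas


def _stage_traits(cfg: ExperimentConfig, variant: str, bundle: SceneBundle,
                  pred_mask: np.ndarray, rgb_canvas: np.ndarray, sr_factor: float,
                  out: Path) -> tuple[pd.DataFrame, dict[str, EvalReport]]:
    scale = GroundScale(gsd_m=bundle.gsd_m, sr_factor=sr_factor)
    min_area = int(cfg.traits.min_area_px * sr_factor**2)
    regions = label_regions(pred_mask, min_area_px=min_area)
    records = []
    for reg in regions:
        extract_region_features(reg, rgb_canvas)
        length_m, width_m = region_to_physical(reg, scale)
        records.append(TraitRecord(
            region_id=reg.region_id, pred_length_m=length_m, pred_width_m=width_m,
            centroid=(reg.centroid[0] / sr_factor, reg.centroid[1] / sr_factor),
        ))
    records, unmatched_r, unmatched_t = match_to_truth(
        records, bundle.truth, max_dist_px=cfg.traits.max_match_dist_px)
    log.info("stage traits[%s]: %d regions, %d matched, %d false pos, %d missed",
             variant, len(records), len(records) - len(unmatched_r),
             len(unmatched_r), len(unmatched_t))

    matched = [r for r in records if r.matched_truth_id is not None]
    evals: dict[str, EvalReport] = {}
    n_needed = (1 if cfg.traits.mlr_mode == "G_only" else 3) + 2
    if len(matched) >= n_needed:
        feats = np.array([
            regions[r.region_id - 1].channel_means[:3] for r in matched
        ])
        spad_true = np.array([r.true_spad for r in matched])
        mlr = fit_spad_mlr(feats, spad_true, mode=cfg.traits.mlr_mode)
        preds, flags = predict_spad(mlr, feats, spad_range=cfg.traits.spad_range)
        for r, p, fl in zip(matched, preds, flags):
            r.pred_spad = float(p)
            r.spad_out_of_range = bool(fl)
        evals["width"] = evaluate_predictions(
            [r.true_width_m * 100 for r in matched],
            [r.pred_width_m * 100 for r in matched])
        evals["length"] = evaluate_predictions(
            [r.true_length_m * 100 for r in matched],
            [r.pred_length_m * 100 for r in matched])
        evals["spad"] = evaluate_predictions(spad_true, preds)
    else:
        log.warning("stage traits[%s]: only %d matched plants; skipping evaluation",
                    variant, len(matched))

    # lengths reported in cm in tables; the API stays in meters
    table = pd.DataFrame([
        {
            "region_id": r.region_id,
            "length_cm": r.pred_length_m * 100,
            "width_cm": r.pred_width_m * 100,
            "spad_pred": r.pred_spad,
            "spad_out_of_range": r.spad_out_of_range,
            "matched_truth_id": r.matched_truth_id,
            "true_length_cm": None if r.true_length_m is None else r.true_length_m * 100,
            "true_width_cm": None if r.true_width_m is None else r.true_width_m * 100,
            "true_spad": r.true_spad,
        }
        for r in records
    ])
    table.to_csv(out / f"traits_{variant}.csv", index=False)
    return table, evals


# --------------------------------------------------------------------------


def run_experiment(cfg: ExperimentConfig, resume: bool = False) -> ComparisonReport:
    """Execute all stages for every requested variant; see module docstring."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not log.handlers:
        logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    t_start = time.time()
    try:
        bundle = _stage_scene(cfg, out, resume)
        tileset = _stage_tiles(cfg, bundle, out)

        seg_accuracy: dict[str, float] = {}
        evals: dict[tuple[str, str], EvalReport] = {}
        for variant in cfg.variants:
            if variant == "multispectral":
                vset = tileset
                sr_factor = 1.0
            elif variant == "rgb":
                vset = _select_bands(tileset, slice(0, 3))
                sr_factor = 1.0
            elif variant == "rgb_sr":
                sr_handle = _stage_sr(cfg, _select_bands(tileset, slice(0, 3)),
                                      out, resume)
                vset = _enhance_tileset(_select_bands(tileset, slice(0, 3)), sr_handle)
                sr_factor = float(sr_handle.config.upscale_factor)
            seg_handle = _stage_segmentation(cfg, variant, vset, out, resume)

            test_tiles = vset.partition("test")
            accs = [pixel_accuracy(predict_mask(seg_handle, t.image),
                                   (t.mask > 0).astype(np.int32)) for t in test_tiles]
            seg_accuracy[variant] = float(np.mean(accs)) if accs else float("nan")
            log.info("variant %s: test pixel accuracy %.4f", variant, seg_accuracy[variant])

            pred = _assemble_mask(seg_handle, vset)
            canvas = _assemble_image(vset)[:, :, :3]
            _table, v_evals = _stage_traits(cfg, variant, bundle, pred, canvas,
                                            sr_factor, out)
            for trait, rep in v_evals.items():
                evals[(variant, trait)] = rep

        report = ComparisonReport(
            seg_accuracy=seg_accuracy,
            evals=evals,
            metadata={
                "seed": cfg.seed,
                "variants": list(cfg.variants),
                "version": __version__,
                "elapsed_s": round(time.time() - t_start, 1),
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            },
        )
        frame = report.to_frame()
        frame.insert(0, "seg_accuracy", [report.seg_accuracy[v] for v in frame["variant"]])
        frame.to_csv(out / "comparison.csv", index=False)
        (out / "metadata.json").write_text(json.dumps(report.metadata, indent=2))
        return report
    finally:
        log.removeHandler(fh)
        fh.close()


def compare_variants(report: ComparisonReport) -> pd.DataFrame:
    """Rank variants per trait by R^2 (higher better), RMSE breaking ties."""
    frame = report.to_frame()
    if frame.empty:
        raise ValueError("report holds no evaluations to compare")
    frame = frame.sort_values(["trait", "r2", "rmse"],
                              ascending=[True, False, True], kind="mergesort")
    frame["rank"] = frame.groupby("trait").cumcount() + 1
    overall = (frame.groupby("variant")["rank"].mean()
               .sort_values(kind="mergesort").rename("mean_rank"))
    frame = frame.merge(overall, on="variant")
    return frame.sort_values(["trait", "rank"]).reset_index(drop=True)
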