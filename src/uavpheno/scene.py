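"""Synthetic stitched-field scenes with exact ground truth.

Emulates nadir imagery of a row-planted rosette crop (e.g. Chinese
cabbage): a textured soil background, elliptical green canopies laid out
in rows with wide inter-row spacing and occasional within-row overlap,
five reflectance bands (R, G, B, RedEdge, NIR) in [0, 1], and a per-plant
truth table. Leaf chlorophyll (SPAD) is linearly coupled to the visible
channel means of each plant plus Gaussian noise, which makes a multiple
linear regression of SPAD on channel means well-posed by construction.

A paired low-/high-resolution degradation model (`degrade_image`)
manufactures the training pairs the super-resolution stage needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .camera import CameraModel, compute_gsd

__all__ = [
    "SceneConfig",
    "PlantTruth",
    "SceneBundle",
    "generate_scene",
    "degrade_image",
    "write_bundle",
    "read_bundle",
]

BAND_NAMES = ("R", "G", "B", "RE", "NIR")

#: native ground scale of the default platform (10 m, 3 um, 5.74 mm)
DEFAULT_GSD_M = compute_gsd(CameraModel())

TRUTH_COLUMNS = [
    "plant_id",
    "center_row_px",
    "center_col_px",
    "semi_axis_a_px",
    "semi_axis_b_px",
    "orientation_rad",
    "length_px",
    "width_px",
    "true_length_m",
    "true_width_m",
    "true_spad",
    "mean_R",
    "mean_G",
    "mean_B",
    "mean_RE",
    "mean_NIR",
]


@dataclass(frozen=True)
class SceneConfig:
    """Layout, spectral and noise parameters of one synthetic field.

    Defaults give a desk-scale field of 4 rows x 5 plants whose canopies
    (semi-axes 14-26 px at ~5.2 mm/px, i.e. ~15-27 cm diameters) and
    reflectances are typical of a mid-season rosette stand.
    """

    field_size: tuple[int, int] = (448, 448)
    n_rows: int = 4
    plants_per_row: int = 5
    row_spacing_px: int = 100
    within_row_spacing_px: int = 80
    jitter_sd_px: float = 3.0
    semi_axis_range_px: tuple[float, float] = (14.0, 26.0)
    overlap_probability: float = 0.15
    spad_range: tuple[float, float] = (15.0, 60.0)
    #: (b0, bR, bG, bB): SPAD = b0 + bR*R + bG*G + bB*B + noise.
    #: Greener (darker, low-reflectance) leaves carry more chlorophyll,
    #: hence the large negative G coefficient.
    spad_coeffs: tuple[float, float, float, float] = (62.0, 25.0, -110.0, 15.0)
    spad_noise_sd: float = 1.5
    #: per-band soil mean reflectance followed by the texture sd (fraction)
    soil_mean: tuple[float, float, float, float, float] = (0.30, 0.25, 0.20, 0.28, 0.30)
    soil_texture_sd: float = 0.05
    canopy_texture_sd: float = 0.08
    gsd_m: float = DEFAULT_GSD_M
    seed: int = 0

    def __post_init__(self) -> None:
        if self.semi_axis_range_px[1] * 2 >= self.row_spacing_px:
            raise ValueError(
                "rows are not separable: 2 * max semi-axis "
                f"({self.semi_axis_range_px[1] * 2:g} px) must be < row_spacing_px "
                f"({self.row_spacing_px} px)"
            )
        if not (0.0 <= self.spad_range[0] <= self.spad_range[1] <= 99.0):
            raise ValueError(f"spad_range must lie within [0, 99], got {self.spad_range}")
        if not 0.0 <= self.overlap_probability <= 1.0:
            raise ValueError("overlap_probability must be in [0, 1]")
        if self.n_rows < 1 or self.plants_per_row < 1:
            raise ValueError("n_rows and plants_per_row must be >= 1")


@dataclass(frozen=True)
class PlantTruth:
    """Ground truth for one plant; extents are measured on the rasterized mask."""

    plant_id: int
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    orientation: float
    length_px: int
    width_px: int
    true_length_m: float
    true_width_m: float
    true_spad: float
    mean_channels: tuple[float, float, float, float, float]


@dataclass
class SceneBundle:
    """One synthetic stitched field: image + instance mask + truth table.

    ``image`` is (H, W, 5) float32 in [0, 1], bands ordered (R, G, B, RE,
    NIR); ``instance_mask`` is (H, W) integer with 0 = background and the
    nonzero labels exactly matching ``truth.plant_id``.
    """

    image: np.ndarray
    instance_mask: np.ndarray
    truth: pd.DataFrame
    gsd_m: float

    def validate(self) -> None:
        if self.image.shape[:2] != self.instance_mask.shape:
            raise ValueError("image and instance_mask dimensions differ")
        labels = set(np.unique(self.instance_mask)) - {0}
        ids = list(self.truth["plant_id"])
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicated plant_id in truth table: {dup}")
        if labels != set(ids):
            raise ValueError(
                f"mask labels {sorted(labels)} do not match truth plant_ids {sorted(ids)}"
            )


def _smooth_noise(shape: tuple[int, int], sd: float, rng: np.random.Generator,
                  smooth_px: float = 3.0) -> np.ndarray:
    """Zero-mean spatially smoothed Gaussian field with pointwise sd ``sd``."""
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, smooth_px)
    s = sm.std()
    if s > 0:
        sm *= sd / s
    return sm


def _ellipse_pixels(center: tuple[float, float], semi_axes: tuple[float, float],
                    theta: float, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of pixels whose centers fall inside the rotated ellipse."""
    cr, cc = center
    a, b = semi_axes
    rmax = max(a, b)
    r0 = max(int(np.floor(cr - rmax)) - 1, 0)
    r1 = min(int(np.ceil(cr + rmax)) + 2, shape[0])
    c0 = max(int(np.floor(cc - rmax)) - 1, 0)
    c1 = min(int(np.ceil(cc + rmax)) + 2, shape[1])
    rr, cc_ = np.mgrid[r0:r1, c0:c1]
    dr = rr - cr
    dc = cc_ - cc
    # rotate into the ellipse frame: u along semi-axis a, v along b
    u = dc * np.cos(theta) + dr * np.sin(theta)
    v = -dc * np.sin(theta) + dr * np.cos(theta)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return rr[inside], cc_[inside]


def generate_scene(config: SceneConfig) -> SceneBundle:
    """Render one synthetic field; bit-identical for a given config.

    Plants are drawn row by row in reading order; where canopies overlap
    the later plant owns the contested pixels, and all truth quantities
    (extents, channel means, SPAD) are measured on the *final* mask so
    that truth and raster never disagree.
    """
    h, w = config.field_size
    # one global seed fans out to independent substreams so that e.g.
    # changing the texture model does not shuffle the layout
    root = np.random.default_rng(config.seed)
    rng_layout, rng_texture, rng_spad = [
        np.random.default_rng(s) for s in root.integers(0, 2**31 - 1, 3)
    ]

    a_min, a_max = config.semi_axis_range_px
    margin_r = (h - (config.n_rows - 1) * config.row_spacing_px) / 2
    margin_c = (w - (config.plants_per_row - 1) * config.within_row_spacing_px) / 2
    slack = a_max + 3 * config.jitter_sd_px
    if margin_r < slack or margin_c < slack:
        raise ValueError(
            f"layout infeasible: field {config.field_size} cannot fit "
            f"{config.n_rows} rows x {config.plants_per_row} plants with "
            f"spacing ({config.row_spacing_px}, {config.within_row_spacing_px}) px "
            f"and canopies up to {a_max:g} px"
        )

    # soil background with multiplicative texture
    image = np.empty((h, w, 5), dtype=np.float32)
    for b, mean in enumerate(config.soil_mean):
        tex = _smooth_noise((h, w), config.soil_texture_sd, rng_texture)
        image[:, :, b] = np.clip(mean * (1.0 + tex), 0.0, 1.0)
    mask = np.zeros((h, w), dtype=np.int32)

    # layout: jittered grid, with occasional neighbor pairs pulled together
    plants = []
    pid = 0
    for i in range(config.n_rows):
        row_c = margin_r + i * config.row_spacing_px
        prev = None
        for j in range(config.plants_per_row):
            pid += 1
            axes = np.sort(rng_layout.uniform(a_min, a_max, 2))[::-1]
            theta = rng_layout.uniform(0.0, np.pi)
            cr = row_c + rng_layout.normal(0.0, config.jitter_sd_px)
            cc = margin_c + j * config.within_row_spacing_px + rng_layout.normal(
                0.0, config.jitter_sd_px
            )
            overlap = prev is not None and rng_layout.uniform() < config.overlap_probability
            if overlap:
                # pull this plant toward its within-row neighbor until the
                # canopies interpenetrate slightly
                gap = cc - prev["cc"]
                want = 0.85 * (axes[0] + prev["axes"][0])
                if gap > want:
                    cc = prev["cc"] + want
            cr = float(np.clip(cr, slack, h - slack))
            cc = float(np.clip(cc, a_max, w - a_max))
            plant = {"pid": pid, "cr": cr, "cc": cc, "axes": axes, "theta": theta}
            plants.append(plant)
            prev = plant

    # per-plant canopy spectra: visible reflectance low (healthy leaves),
    # red-edge/NIR strongly elevated versus soil
    for p in plants:
        base = np.array(
            [
                rng_texture.uniform(0.04, 0.10),   # R
                rng_texture.uniform(0.12, 0.30),   # G
                rng_texture.uniform(0.03, 0.08),   # B
                rng_texture.uniform(0.34, 0.44),   # RE
                rng_texture.uniform(0.44, 0.58),   # NIR
            ]
        )
        rr, cc_ = _ellipse_pixels((p["cr"], p["cc"]), tuple(p["axes"]), p["theta"], (h, w))
        if rr.size == 0:
            raise ValueError(f"plant {p['pid']} rasterized to zero pixels")
        tex_field = _smooth_noise((h, w), config.canopy_texture_sd, rng_texture)
        t = 1.0 + tex_field[rr, cc_]
        for b in range(5):
            image[rr, cc_, b] = np.clip(base[b] * t, 0.0, 1.0)
        mask[rr, cc_] = p["pid"]

    # truth measured on the final raster (overlaps resolved)
    records = []
    b0, bR, bG, bB = config.spad_coeffs
    for p in plants:
        rr, cc_ = np.nonzero(mask == p["pid"])
        if rr.size == 0:
            raise ValueError(
                f"plant {p['pid']} fully occluded by a neighbor; lower "
                "overlap_probability or enlarge spacing"
            )
        ext_r = int(rr.max() - rr.min() + 1)
        ext_c = int(cc_.max() - cc_.min() + 1)
        length_px, width_px = max(ext_r, ext_c), min(ext_r, ext_c)
        means = tuple(float(image[rr, cc_, b].mean()) for b in range(5))
        spad = b0 + bR * means[0] + bG * means[1] + bB * means[2]
        spad += rng_spad.normal(0.0, config.spad_noise_sd)
        records.append(
            PlantTruth(
                plant_id=p["pid"],
                center=(float(rr.mean()), float(cc_.mean())),
                semi_axes=(float(p["axes"][0]), float(p["axes"][1])),
                orientation=float(p["theta"]),
                length_px=length_px,
                width_px=width_px,
                true_length_m=length_px * config.gsd_m,
                true_width_m=width_px * config.gsd_m,
                true_spad=float(spad),
                mean_channels=means,
            )
        )

    truth = pd.DataFrame(
        [
            {
                "plant_id": t.plant_id,
                "center_row_px": t.center[0],
                "center_col_px": t.center[1],
                "semi_axis_a_px": t.semi_axes[0],
                "semi_axis_b_px": t.semi_axes[1],
                "orientation_rad": t.orientation,
                "length_px": t.length_px,
                "width_px": t.width_px,
                "true_length_m": t.true_length_m,
                "true_width_m": t.true_width_m,
                "true_spad": t.true_spad,
                "mean_R": t.mean_channels[0],
                "mean_G": t.mean_channels[1],
                "mean_B": t.mean_channels[2],
                "mean_RE": t.mean_channels[3],
                "mean_NIR": t.mean_channels[4],
            }
            for t in records
        ],
        columns=TRUTH_COLUMNS,
    )
    bundle = SceneBundle(image=image, instance_mask=mask, truth=truth, gsd_m=config.gsd_m)
    bundle.validate()
    return bundle


def degrade_image(image: np.ndarray, factor: int, blur_sd: float = 1.0,
                  noise_sd: float = 0.01, seed: int = 0) -> np.ndarray:
    """Low-resolution degradation: Gaussian blur, block-mean downsample, noise.

    Models the loss of detail between an enhanced-resolution target and
    the native capture; used to manufacture paired training data for the
    super-resolution stage.
    """
    if image.ndim == 2:
        image = image[:, :, None]
        squeeze = True
    else:
        squeeze = False
    h, w, c = image.shape
    if h % factor or w % factor:
        raise ValueError(f"factor {factor} does not divide image dimensions {(h, w)}")
    out = np.empty((h // factor, w // factor, c), dtype=np.float32)
    rng = np.random.default_rng(seed)
    for b in range(c):
        band = image[:, :, b].astype(np.float64)
        if blur_sd > 0:
            band = ndimage.gaussian_filter(band, blur_sd)
        band = band.reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))
        out[:, :, b] = band
    if noise_sd > 0:
        out += rng.normal(0.0, noise_sd, out.shape).astype(np.float32)
    out = np.clip(out, 0.0, 1.0, out=out)
    return out[:, :, 0] if squeeze else out


def write_bundle(bundle: SceneBundle, path: str | Path) -> None:
    """Persist a scene as image.tif (float32, 5 bands), mask.tif, truth.csv."""
    bundle.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path / "image.tif", bundle.image)
    tifffile.imwrite(path / "mask.tif", bundle.instance_mask.astype(np.uint16))
    truth = bundle.truth.copy()
    truth.insert(0, "gsd_m", bundle.gsd_m)
    truth.to_csv(path / "truth.csv", index=False)


def read_bundle(path: str | Path) -> SceneBundle:
    """Load a scene written by :func:`write_bundle`; validates invariants."""
    path = Path(path)
    image = tifffile.imread(path / "image.tif")
    mask = tifffile.imread(path / "mask.tif").astype(np.int32)
    truth = pd.read_csv(path / "truth.csv")
    missing = [c for c in ["gsd_m", *TRUTH_COLUMNS] if c not in truth.columns]
    if missing:
        raise ValueError(f"truth.csv is missing columns {missing}")
    if truth["plant_id"].duplicated().any():
        dup = sorted(truth.loc[truth["plant_id"].duplicated(), "plant_id"].unique())
        raise ValueError(f"truth.csv has duplicated plant_id: {dup}")
    gsd = float(truth["gsd_m"].iloc[0]) if len(truth) else DEFAULT_GSD_M
    bundle = SceneBundle(
        image=image, instance_mask=mask, truth=truth.drop(columns=["gsd_m"]), gsd_m=gsd
    )
    bundle.validate()
    return bundle
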