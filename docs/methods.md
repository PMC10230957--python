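# Methods

## Scope and data model

The package implements a complete desk-scale analogue of a UAV
phenotyping campaign for row-planted rosette crops: synthetic stitched
scenes stand in for orthomosaics, and every downstream stage — tiling,
super-resolution, semantic segmentation, instance extraction, trait
photogrammetry and SPAD regression — operates exactly as it would on
real rasters. All imagery is reflectance-like float in [0, 1]; 8-bit
conversion happens only at I/O boundaries, which keeps the PSNR `MAX`
convention explicit (1.0 internally, 255 for 8-bit exports).

## Photogrammetric scale model

GSD = H·a/f, with H in meters, a in micrometers and f in millimeters at
the constructor surface and everything converted to meters on entry
(mixed units are the single most common source of silent 10³ errors in
this calculation). Defaults are the reference platform: H = 10 m,
a = 3 μm, f = 5.74 mm, 1600 × 1300 px, giving 5.2265 mm/px, an
8.36 m × 6.79 m frame and a 3.18 m extent for a 608-px tile. The
`GroundScale` type pairs the native GSD with the super-resolution
factor (`sr_factor` ≥ 1); physical sizes measured on enhanced masks are
`n_px · gsd / sr_factor`. Keeping the factor in the scale object rather
than the camera means one camera serves native and enhanced pipelines
and the division cannot be forgotten. Off-nadir geometry, lens
distortion and terrain relief are out of scope: the scene is treated as
flat nadir imagery at fixed height. The platform's imaging-angle
setting is metadata only; it enters no equation.

Lengths are returned in meters by the API and printed in centimeters in
tables, where rosette diameters (~20–60 cm) are most readable.

## Synthetic scenes

`generate_scene` renders, from one seed (fanned out into independent
layout/texture/noise substreams):

- **Soil**: per-band mean reflectance (default R 0.30, G 0.25, B 0.20,
  RE 0.28, NIR 0.30) with multiplicative smoothed Gaussian texture
  (sd 5%).
- **Canopies**: rotated ellipses on a jittered row grid (default 4 rows
  × 5 plants, 100 px row spacing, 80 px within-row spacing, semi-axes
  14–26 px ≈ 15–27 cm diameters at the default GSD). With probability
  0.15 a within-row neighbor pair is pulled together until the canopies
  interpenetrate, reproducing the overlap failure mode that makes
  within-row width the hardest trait in the field. Later plants own
  contested pixels.
- **Spectra**: visible reflectance low (healthy leaves), RedEdge/NIR
  strongly elevated over soil — plant pixels separate from soil in
  NIR − R almost everywhere, which is what makes the multispectral
  segmentation variant easy and realistic.
- **SPAD**: true SPAD = b0 + bR·R̄ + bG·Ḡ + bB·B̄ + ε with defaults
  (62, 25, −110, 15) and ε ~ N(0, 1.5). The channel means are the
  *measured* means over the plant's final rasterized pixels, so the
  generator and the trait module's regression are mutually consistent
  by construction; with ε = 0 the coefficients are recovered to
  numerical precision. The large negative G coefficient encodes that
  darker-green (lower G reflectance) leaves carry more chlorophyll; the
  defaults place SPAD in a realistic 25–50 band. A linear
  SPAD–reflectance coupling is an assumption — it is exactly the
  assumption under which a multiple linear regression on channel means
  is well-posed, and nothing in the generator validates it against real
  canopies.

Truth tables store extents measured on the final mask (so truth and
raster can never disagree), the meter extents as pixel extents × GSD,
and the measured channel means. What the generator does **not**
emulate: radiative transfer, shadows, wind blur, stitching seams,
perspective. Passing desk-scale tests therefore demonstrates internal
consistency of the pipeline, not field accuracy.

`degrade_image` (Gaussian blur → factor-k block mean → additive noise,
clipped) manufactures the paired low/high-resolution data the SR stage
trains on; real campaigns rarely fly paired heights, so a degradation
model of this kind is the standard stand-in.

## Tiling and splits

Zero-overlap reading-order grid; ragged edges are dropped, not padded
(padding would distort label statistics at scene borders). Default tile
608 px as in field practice, 96 px in desk-scale configs so a CPU can
train the segmenter in minutes. Augmentation is the closed set
{identity, hflip, vflip, transpose} (factor 4 — the minimal closed
group containing the two flips), applied only to the training
partition; augmented tiles inherit their parent's split, so no derived
view of a held-out tile can leak into training. The 8:1:1 split floors
each partition and hands remainders out train → test → validation.
Instance masks are collapsed to semantic plant/soil before one-hot
encoding; instances are recovered downstream by connected components.

## Neural backend

No deep-learning framework is assumed: `uavpheno.nn` provides NCHW
conv2d (im2col, stride 1/2), 2×2 max pooling, nearest upsampling, pixel
shuffle, dropout, Adam, and softmax-CE / MSE / BCE-with-logits losses,
all with explicit forward/backward passes checked against central
finite differences (float64, agreement ~1e-9). Weights are
He-initialized from per-layer seeded generators, so training is
bit-reproducible on one backend; exact histories across BLAS builds are
not guaranteed and are not asserted.

## Super-resolution

Generator: input conv + ReLU → residual blocks (2 × conv3×3 with a
residual edge; default 2 blocks, 16 channels) → post-conv with a global
skip → two sub-pixel ×2 stages → output conv. Two deliberate design
choices:

- **Global residual learning.** The output head is zero-initialized and
  added to the nearest-upsampled input, so the untrained generator *is*
  the nearest-neighbor baseline and training can only sharpen it. At
  toy step budgets (tens of epochs on ≤16 pairs) a from-scratch
  generator spends its entire budget learning global brightness and
  never reaches the baseline it is compared against.
- **Perceptual loss without downloads.** The default content loss is an
  MSE in the feature space of a small fixed random convolutional
  extractor; a pretrained classifier's features can be plugged in where
  available, but the package is hermetic by default. For PSNR-oriented
  evaluation the pixel-MSE content loss is the right configuration
  (PSNR is a monotone function of pixel MSE), and the desk-scale
  quality check uses it; the feature-space + adversarial default is for
  perceptual training.

Training alternates discriminator first, then generator, per batch; the
adversarial term uses the non-saturating BCE objective with weight 1e-3.
SR operates on RGB only — multispectral rasters are never enhanced.

PSNR is 10·log10(MAX²/MSE) with an `inf` sentinel at zero MSE; SSIM is
the standard windowed index (scikit-image implementation, channel-mean
for multichannel).

## Segmentation

The segmenter is an encoder–decoder with skip connections totalling 10
3×3 convolutions: two double-conv encoder levels, a double-conv bridge
with dropout, and two decoder levels whose inputs concatenate the
matching encoder features (the 1×1 class head and the two
upsample-convs sit outside the count). `conv_layer_count` generalizes
as 4·levels + 2. Defaults keep the published recipe (batch 2, learning
rate 1e-5, 120 epochs, no pretrained weights); desk-scale configs use
base_filters 8, batch 4, lr 2e-3 and ≤ 10 epochs, which reach > 0.99
held-out pixel accuracy on synthetic scenes in under a minute of CPU —
the synthetic NIR/colour contrast makes the task genuinely easy, which
is the point of the closure tests, not evidence of field performance.
Adam is used throughout (the classical choice for this architecture
family; recorded in the config for auditability). The epoch with the
lowest validation loss is checkpointed and restored. Accuracy is
pixel-level; object-level detection (matched/unmatched plants) is
reported separately by the matching stage.

## Trait extraction and evaluation

Instances are 8-connected components of the semantic mask (diagonal
touch joins), filtered by a minimum area (default 30 px; scaled by
sr_factor² on enhanced masks) and renumbered in reading order of the
bounding-box corner, which makes region ids deterministic. Length and
width are the max/min bounding-box extents — orientation-free, matching
how rosette diameter pairs are measured with a ruler in the field; all
coordinates are 0-based with half-open boxes, so extent = max − min.
Channel means are taken over region pixels only (background removed),
never over the bounding box.

SPAD regression is ordinary least squares with intercept, on Ḡ alone or
on (R̄, Ḡ, B̄) (statsmodels backend; raw means, no rescaling). Rank
deficiency fails with the offending columns named. Predictions outside
the physical SPAD range are flagged, never clipped.

Evaluation statistics follow the printed definitions exactly:
R² = SSR/SST (explained-variance form, which exceeds 1 when the
predictions over-disperse — the hand-checked case actual (1,2,3) vs
predicted (1,2,4) gives 2.5); the conventional 1 − SSE/SST is available
as `r2_mode="residual"` and both can be reported side by side. RMSPE is
the root mean square of the *fractional* errors
√(n⁻¹Σ((yᵢ−ŷᵢ)/yᵢ)²) — the alternative reading of the formula (a
percentage of the mean) was rejected and the chosen form is pinned by
hand-computed tests. Degenerate inputs (zero variance in the reference,
zero reference values for RMSPE, n < 2) raise instead of returning
misleading numbers.

Prediction-to-truth pairing is greedy mutual-nearest centroid matching
within a radius (default 25 px), distance ties broken by reading order;
unmatched predictions and truths are reported separately as false
positives and misses. Field protocols rarely state their pairing rule;
greedy mutual-nearest is the simplest deterministic choice.

## Experiment orchestration

The three variants (multispectral / rgb / rgb_sr) share one scene, one
tiling and one split, so comparisons are paired — only input bands and
enhancement differ. For rgb_sr, tiles are SR-enhanced ×4, masks
upscaled by nearest neighbor, and the trait stage divides by
sr_factor = 4; region centroids are rescaled before matching. The SPAD
model is fitted on the matched plants of the run and evaluated on the
same records (the in-sample protocol a small field campaign with ~20
reference plants effectively uses). Each stage persists artifacts
(scene TIFFs, tile index, model checkpoints, history CSVs, trait and
comparison CSVs, run log) and `resume=True` reuses whatever exists.
Every random draw derives from the single experiment seed. Ranking is
per trait by R² (higher first) with RMSE as tie-break, plus a mean-rank
summary across traits.

## Problem sizes and numerical choices

Desk-scale defaults were chosen once as the smallest sizes at which
every stage behaves like its field-scale counterpart: scenes of
384–576 px with 12–30 plants, 96-px tiles (48 px in the smallest
end-to-end runs), SR training on ≤ 16–20 pairs of 24→96 px for ≤ 50
epochs, segmentation on ~30–120 tiles for ≤ 10 epochs. Argmax ties in
prediction break toward the lower class index; max-pool gradient flows
to the first argmax; dropout is inactive at inference; PSNR of
identical images is `inf` by convention.

## Known limitations

- Synthetic scenes are radiometrically idealized; none of the reported
  desk-scale accuracies transfer to field imagery.
- Semantic segmentation + connected components cannot split canopies
  that truly merge; heavily overlapped neighbors appear as one region
  and surface as a miss plus a biased width (the generator reproduces
  this failure mode on purpose).
- The explained-variance R² is not bounded above by 1; rankings based
  on it reward over-dispersion symmetrically with fit. The residual
  form is provided for cross-checks.
- The numpy backend is single-threaded per operation and intended for
  desk-scale problems, not for training at campaign scale.
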