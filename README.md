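# uavpheno

High-throughput phenotyping of row-planted rosette crops (e.g. Chinese
cabbage, *Brassica rapa* ssp. *pekinensis*) from multiband nadir UAV
imagery. The package turns a stitched five-band field raster
(R, G, B, RedEdge, NIR) into per-plant physical canopy width and length
and a chlorophyll estimate (SPAD value), through four stages:

1. **Photogrammetric scaling.** At flight height *H* with pixel pitch
   *a* and focal length *f*, one pixel covers a ground sampling distance
   GSD = *H·a/f*. A plant spanning *n* pixels is *n*·GSD meters across;
   masks measured on resolution-enhanced imagery divide by the
   enhancement factor.
2. **Super-resolution (SRGAN).** A residual convolutional generator with
   two sub-pixel ×2 stages upscales RGB tiles four-fold; a convolutional
   discriminator and a perceptual content loss drive alternating
   adversarial training. Quality is tracked with PSNR and SSIM.
3. **Semantic segmentation (UNet).** A 10-convolution encoder–decoder
   with skip connections classifies every pixel as plant or soil,
   trained with categorical cross entropy on one-hot masks from
   608-px-style tiles (desk-scale configs use 96 px) split 8:1:1 with
   flip/transpose augmentation of the training partition only.
4. **Trait extraction.** Plant instances are 8-connected components of
   the predicted mask; each region's bounding-box extents become width
   and length (orientation-free: length ≥ width) in centimeters via the
   GSD, and SPAD is predicted by multiple linear regression on the
   region's mean R, G, B reflectances (or G alone). Predictions are
   scored with R² = Σ(ŷᵢ−ȳ)²/Σ(yᵢ−ȳ)² (explained-variance form),
   RMSPE = √(n⁻¹Σ((yᵢ−ŷᵢ)/yᵢ)²) and RMSE = √(n⁻¹Σ(yᵢ−ŷᵢ)²).

Because public drone campaigns of this kind are rarely deposited, the
package ships a synthetic-scene generator (`uavpheno.scene`) that
renders textured soil, elliptical canopies in rows with occasional
within-row overlap, vegetation-like spectra whose SPAD is linearly
coupled to the visible channel means, and exact per-plant ground truth
— so the whole pipeline is testable end to end on any machine. The
neural stages run on a small self-contained numpy backend
(`uavpheno.nn`) validated by finite-difference gradient checks.

Three experiment variants mirror a typical study design and share one
scene, tiling and split: `multispectral` (5 bands), `rgb`, and `rgb_sr`
(RGB enhanced ×4 before segmentation).

## Worked example

```python
from uavpheno.camera import (CameraModel, GroundScale, compute_gsd,
                             image_footprint, px_to_length)

cam = CameraModel()                 # 10 m flight, 3 um pitch, 5.74 mm lens
gsd = compute_gsd(cam)
fp = image_footprint(cam)
print(f"GSD: {gsd*1e3:.2f} mm/px")
print(f"frame: {fp.length_m:.2f} m x {fp.width_m:.2f} m ({fp.area_m2:.2f} m^2)")
print(f"608-px tile: {px_to_length(608, GroundScale(gsd_m=gsd)):.2f} m")
print(f"plant of 61 x 41 px: {px_to_length(61, GroundScale(gsd))*100:.1f} cm"
      f" x {px_to_length(41, GroundScale(gsd))*100:.1f} cm")
```

prints

```
GSD: 5.23 mm/px
frame: 8.36 m x 6.79 m (56.82 m^2)
608-px tile: 3.18 m
plant of 61 x 41 px: 31.9 cm x 21.4 cm
```

i.e. each pixel covers 5.23 mm of ground, one full camera frame images
an 8.36 m × 6.79 m footprint, a 608-px tile spans 3.18 m, and a
segmented region of 61 × 41 px corresponds to a rosette of roughly
32 cm × 21 cm.

The full experiment runs from one YAML config:

```sh
uavpheno init-config experiment.yaml
uavpheno run-all --config experiment.yaml --seed 7
uavpheno compare --config experiment.yaml --seed 7
```

`run-all` writes the scene, tile index, model checkpoints, per-plant
trait tables (`traits_<variant>.csv`, lengths in cm), an evaluation
table (`comparison.csv` with R²/RMSPE/RMSE per variant and trait) and a
run log into the configured output directory; `compare` ranks the
variants per trait by R² with RMSE as tie-break. Individual stages are
available as `generate`, `tile`, `train-sr`, `enhance`, `train-seg`,
`traits`, `evaluate` and resume from artifacts already on disk.

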