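# spineseg

Automatic vertebral-body segmentation for 2D sagittal lumbar-spine slices
(single-slice DICOM or PNG), aimed at researchers who need per-vertebra
outlines, areas and agreement statistics without manual contouring.

The pipeline chains four classical components:

1. **Initial filtration** — cubic-convolution upsampling, intensity-
   inhomogeneity (IIH) correction with a multiplicative exponential bias
   model `b(d) = exp(-λ d)` fitted in depth `d` from the skin line, and a
   selective Gaussian filter whose intensity window widens with depth by
   the same factor.
2. **Vertebra detection** — a Viola–Jones style cascade of AdaBoost stages
   over variance-normalized Haar-like features (edge, line,
   center-surround, optional diagonal kinds), trained with thin-plate-
   spline (TPS) augmented positives and hard negatives mined from
   vertebra-free slices reconstructed by harmonic inpainting. A median-area
   band filter removes off-size boxes.
3. **Landmark localization** — a patch-based Active Appearance Model: a
   Point Distribution Model (generalized Procrustes + PCA over 16-point
   shapes, `s = s̄ + Φb` under a global similarity) coupled with per-landmark
   patch PCA, fitted coarse-to-fine by Lucas–Kanade Gauss–Newton iterations.
   Five inverse-compositional variants are provided: POIC (project-out),
   SIC (simultaneous), AIC (alternating), MAIC (modified alternating), and
   WIC (Wiberg elimination of appearance parameters, the default).
4. **Contour interpolation and evaluation** — the 16 fitted landmarks are
   interpolated with a closed centripetal Catmull–Rom spline (knot
   increments `‖ΔP‖^0.5`), rasterized by the even-odd rule, and scored
   against references with the area fractions

   TPF = |A_S ∩ A_T| / |A_T|, FNF = |A_T − A_S| / |A_T|,
   FF = 1 − (|A_FP| + |A_FN|) / |A_T|,

   reported as percentages with the mean ± 1.96 σ/√n convention. Area
   agreement between raters uses the two-way intraclass correlation
   coefficient (single and average measures).

A seeded phantom generator (`spineseg.synthetic`) renders sagittal-spine
look-alikes — bright vertebral bodies, darker discs, spinal canal, a
subcutaneous fat band, exponential coil falloff and Gaussian noise — with
exact 16-point ground truth, so the entire pipeline trains and evaluates
without any clinical data.

## Worked example

```python
import numpy as np
from spineseg import pipeline, metrics, contour, aam
from spineseg.synthetic import generate_dataset

config = pipeline.resolve_config()
train = generate_dataset(30, seed=11)      # 30 phantom slices, 5 vertebrae each
test = generate_dataset(3, seed=99)

model = pipeline.train_aam(train, config)  # shape PCA + per-landmark patch PCA
print(f"shape components: {model.shape.n_components}")

item = test["items"][0]
pre = pipeline.preprocess_image(item["image"], config)
box, lms, gt_mask = item["truths"][0]

init = aam.perturb_shape(lms, noise=config["init"], seed=3)
result = aam.fit(pre, model, init, {"algorithm": "WIC", "n_iterations": 25})

auto = contour.rasterize(contour.catmull_rom_closed(result.final.points), pre.shape)
rep = metrics.fractions(auto, gt_mask)
print(f"TPF = {rep.TPF:.2f}%  FNF = {rep.FNF:.2f}%  FF = {rep.FF:.2f}%")
print(f"point-to-point error: {aam.point_to_point_error(init, lms):.2f} px (init) "
      f"-> {aam.point_to_point_error(result.final, lms):.2f} px (fitted)")
area = contour.area_mm2(contour.catmull_rom_closed(result.final.points), pre.spacing)
print(f"vertebral body area: {area:.1f} mm^2")
```

Output:

```
shape components: 23
TPF = 99.30%  FNF = 0.70%  FF = 98.61%
point-to-point error: 9.17 px (init) -> 1.03 px (fitted)
vertebral body area: 1291.8 mm^2
```

The fit recovers the vertebral outline from a deliberately displaced
initialization (9.2 px mean landmark error) down to about one pixel; the
resulting mask overlaps the ground-truth body almost completely (FF is the
combined-error fraction — 100% means a perfect match, and it falls by one
point per percent of missed or spurious area).

## Command line

Every stage is exposed as a subcommand, all seeded and reproducible
(`config.yaml` is written next to each run's outputs):

```bash
spineseg --seed 11 synth --n 50 --out data/
spineseg --seed 11 train-detector --data data/ --out models/cascade.json
spineseg --seed 11 train-aam      --data data/ --out models/aam.json
spineseg --seed 11 segment --image slice.png \
    --detector models/cascade.json --aam models/aam.json --out out/
spineseg evaluate --pred out/ --refs expert/ --out report.csv
spineseg --seed 11 compare-algorithms --data data/ --aam models/aam.json --out table.csv
spineseg --seed 11 crossval --data data/ --k 10 --out cv.csv
```

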