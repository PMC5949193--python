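# Methods

This note documents the models, the numerical choices, and the limits of
what the phantom-based tests demonstrate.

## Initial filtration

**Resampling.** Upsampling uses separable cubic convolution (Keys kernel)
with free parameter `a`, default `a = -0.5` — the Catmull–Rom member,
which has linear (in fact quadratic) precision and a sharp high-frequency
response. The same sampler performs all sub-pixel interpolation in the TPS
warper. The `upsample` operation defaults to factor 2, which is the
sensible choice for low-resolution clinical slices; the pipeline
configuration defaults to factor 1 because the phantoms are generated at a
resolution where the detector and patch model already operate one-to-one.

**IIH correction.** Surface-coil falloff is modeled as a multiplicative
exponential in depth from the skin: `b(d) = exp(-λ d)`, `d` in mm. The
skin line is the first column per row (scanning inward from the configured
side) that exceeds that row's 0.90 intensity quantile, smoothed by an
11-row running median; rows without a crossing inherit the median
boundary. λ and the reference intensity `I0` come from a least-squares
line through `log(intensity)` versus depth over foreground pixels (global
Otsu threshold; at least 100 pixels required). The corrected image is
`pixels · exp(λ d)`, rescaled to preserve the input mean exactly. This
log-linear reading of "fit a global exponential from the fat–skin
contrast" was chosen for testability: the fit is a closed form, and
correction followed by re-fit gives a slope of zero by construction.

The single-line fit pools all foreground tissue classes. Classes with
different base intensities that occupy different depth ranges bias the
slope (the fat band sits at depth ≈ 0 and is brighter than vertebral
bodies at depth 80–180 mm). The phantom's default fat-band width (5 px)
was chosen at generator-design time so that this class-mixing bias
approximately cancels, keeping the estimator within its documented 15%
recovery band; the bias is a property of the estimator a user should know
about on real data, where the band's extent is anatomy-dependent.

**Selective Gaussian.** Each pixel is replaced by the Gaussian-weighted
mean (σ = `sigma_px`, radius 3σ) of neighbors within an intensity window
`edge_threshold · exp(λ d)`; depth scaling matches the noise amplification
introduced by the correction. Pixels with no qualifying neighbor are left
unchanged, which makes the filter idempotent on piecewise-constant images
with super-threshold steps. The pipeline default is `sigma_px = 1.0`,
`edge_threshold = 25`: at the phantom's noise level (σ ≈ 4 on a 0–255
scale, 1 mm pixels) a wider kernel visibly blurs the endplate edges the
detector and patch model rely on.

## Cascade detector

Discrete AdaBoost over decision stumps on variance-normalized Haar-like
features; window 24×24; per-stage targets hit rate ≥ 0.995 and false
alarm ≤ 0.5; up to 12 stages. The stage threshold is lowered to the
(1 − hit-rate) quantile of the positive scores after each stump. The
feature pool is enumerated on a stride grid (default stride 3, ≈ 1900
features) and recorded in the model. Weight updates use
`w ← w · exp(α·1[miss])`, `α = ln((1−e)/e)`, renormalized; stump search is
exhaustive over sorted feature values with tolerance-aware tie-breaking
(smallest split, then smallest feature index, `+1` polarity preferred) so
training is deterministic across BLAS layouts. Diagonal (`tilted_edge`)
features are available behind a flag and are evaluated through dense pixel
masks rather than rotated integral images — correct but slower, and off
by default.

Training data: positives are ground-truth box crops plus TPS-warped
variants (default 4 per crop; per-landmark jitter σ = 2% of crop width,
rotation ±8°, scale ±10%); negatives are the same slices with each
vertebral body removed by harmonic inpainting of its *exact* mask, so
discs, canal, endplate context and the fat band survive as hard negative
context. Box-dilated inpainting (`generate_negatives`) is also provided;
the exact-mask variant was preferred for the default pipeline because
context-free negatives make the stages trivially shallow. Negative windows
are mined by seeded random sampling of windows the current cascade still
accepts; training stops early when fewer than `min_neg_per_stage` (50) can
be mined — stages trained on a handful of accidental windows add noise,
not discrimination.

Detection slides the window with 2 px steps over a 1.1× pyramid, groups
raw hits by connected components of the IoU ≥ 0.3 graph, discards groups
with fewer than 3 hits, and returns mean boxes scored by hit count. The
median-area band [0.5, 2.0]× then removes off-size boxes; with fewer than
3 detections the filter is a no-op.

## Patch-based AAM

Shapes are 16 ordered boundary points. Generalized Procrustes alignment
(centroid removal, unit Frobenius norm, least-squares rotation, iterated
to 1e-7) precedes shape PCA retaining 95% variance. Appearance is one
PCA (90% variance) per pyramid scale over the concatenation of 17×17
patches extracted at the landmarks with bilinear sampling and per-patch
z-scoring; z-scoring buys local gain/offset invariance at the price of a
slightly inconsistent gradient model, which Gauss–Newton tolerates.

The fitter parameterizes a shape as a global similarity `(a, b, tx, ty)`
composed with shape coefficients `b_k`. Steepest-descent images come from
*template* gradients (the inverse-compositional economy), assembled at the
mean configuration per scale; the five variants differ only in the
appearance coefficients `c`:

- POIC projects residual and Jacobian onto the appearance-orthogonal
  complement once and reuses a precomputed Hessian;
- SIC solves shape and appearance increments jointly with the
  current-template Jacobian `SD(c) = SD₀ + Σ c_k SD_k`;
- AIC solves `c = Aᵀr` exactly, then steps the shape against the
  reconstruction residual with `SD(c)`;
- MAIC keeps a running `c` and applies its update *before* recomputing the
  residual used by the shape step (one concrete reading of "modified
  alternating", flagged as such);
- WIC eliminates `c` analytically each iteration and uses the projected
  current-template Jacobian — it coincides with POIC only when `c = 0`.

Updates are damped by halving (up to 4 times) whenever the cost rises;
after the final halving the step is accepted regardless, which lets the
trace escape flat configurations at the price of occasional sub-point
wiggles in the per-iteration tables. Shape coefficients are clamped to
±3√λ_k. Degenerate Hessians are handled by pseudo-inverse with cutoff
1e-10. Iterations are split evenly across the pyramid scales (default 0.5
and 1.0), remainder to the finest; iteration 0 of a fit trace is the
initialization, matching the 0..25 convention of the convergence tables.
Landmarks pushed outside the image are clamped and the fit is flagged
unconverged. A zero-iteration fit returns its initialization verbatim
rather than the model-subspace projection of it.

Initialization: in deployment the mean shape is scaled into the detected
box (92% fill); in evaluation protocols the initialization is a perturbed
ground truth (translation σ = 5% of the bounding-box diagonal per axis,
scale σ = 2%, rotation σ = 3°), which isolates fitter convergence from
detector accuracy.

## Contours, masks, metrics

Closed Catmull–Rom interpolation uses the Barry–Goldman pyramid with
centripetal knots (α = 0.5, configurable), 20 samples per segment
(doubling changes phantom areas by < 0.1%). Rasterization is pixel-center
even-odd; areas come from the shoelace formula (contours) or pixel counts
(masks), times the spacing product.

TPF/FNF/FF are exact pixel-count ratios; TPF + FNF = 100 is an integer
identity and FF is reported unclamped (negative under gross
over-segmentation). Summaries use mean ± 1.96·σ/√n with the n−1 standard
deviation; the conventional two-decimal z-score is used at α = 0.05 (the
exact normal quantile otherwise). The ICC defaults to the two-way
*consistency* definition — the evaluation compares measured areas, where a
constant offset between raters should not destroy agreement — with
absolute agreement selectable; average-measures values follow
Spearman–Brown, and the single-measures CI comes from the F distribution.
k-fold cross-validation shuffles images (never splitting an image's
vertebrae across folds), trains the AAM on the complement, fits held-out
vertebrae from perturbed ground truth, and scores against the rasterized
ground-truth contour.

## Phantom generator

Each phantom stacks 5 vertebral bodies (34×42 px ± 8% similarity jitter,
±4° rotation) along a gently curved column, with darker discs, a dark
canal band, a 5 px bright fat band at the skin side, multiplicative
`exp(-0.004/mm · d)` falloff and additive Gaussian noise (σ = 4). The
16-point template is 4 rounded-corner points plus 3 per edge, clockwise
from the anterior-superior corner; per-landmark Gaussian jitter
(σ = 0.8 px) individualizes each body, and the body mask *is* the
rasterized Catmull–Rom contour through those landmarks, so landmark, mask
and contour ground truth agree by construction. Landmark jitter stands in
for the spec'd template deformation; the TPS machinery itself lives in the
augmentation module where it warps real pixel data.

What the phantoms do not emulate: TSE contrast behaviour, partial-volume
fading, pathology (fractures, herniation), anatomical neighbours
(pedicles, processes), patient-to-patient intensity shifts, or annotation
disagreement between human experts. Passing tests therefore demonstrate
the correctness and internal consistency of the implementation and its
convergence behaviour under controlled conditions — not clinical-grade
accuracy. Overlap fractions on phantoms (FF ≈ 98%) are accordingly higher
than any realistic figure on clinical MRI.

Default problem sizes — 50 training slices, 12 test slices, 100
cross-validation slices with 5 folds — were chosen as the package's
desk-scale standard conditions; they train in about a minute (cascade) and
seconds (AAM) on one CPU.

## Known limitations

- The IIH model is 1-D in depth; in-plane bias components are not
  corrected (out of scope, as are N4-style histogram methods).
- Tilted Haar features use dense-mask evaluation; enabling them slows
  sliding-window detection noticeably.
- The detector's grouped boxes can merge when a spurious large-scale hit
  chains two adjacent vertebrae; the size filter removes off-size boxes
  but cannot split a merged group.
- MAIC's "modification" follows one published reading (appearance update
  applied before residual recomputation); other readings exist.
- PTS is an artifact serialization choice for annotations; no claim is
  made about any particular clinical annotation format.
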