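# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the `axr` toolkit.

## Image model

All operators work on a single currency: a 2-D float64 intensity raster in
`[0, 1]`, row-major, origin top-left, with higher values brighter
(bright-soft-tissue convention).  Rasters smaller than 8×8 are rejected —
tile grids, blur radii and lesion geometry all assume a non-degenerate
image.  Integer containers are normalised by the full representable range
of their bit depth rather than the observed min/max, so the same scene at
two exposures stays distinguishable.  DICOM reads apply rescale
slope/intercept, window to the stored min/max, and invert MONOCHROME1
photometric interpretation so that the brightness convention holds.
Three-channel classifier inputs are `(3, H, W)` stacks whose planes obey
the same invariants.

## Enhancement operators

All convolutions use reflective boundaries: zero padding would create a
dark frame that the equalisation steps downstream would amplify into a
strong artefact.

* **sharpen** — 3×3 convolution, kernel constrained to sum to 1 so flat
  regions are preserved.  Default kernel `[[0,−1,0],[−1,5,−1],[0,−1,0]]`
  (identity plus negative Laplacian), the standard choice when no kernel
  is otherwise specified; configurable.
* **hist_equalize** — 256-bin histogram; mapping
  `(cdf − cdf_min)/(1 − cdf_min)` with `cdf_min` taken at the lowest
  occupied bin.  A constant image is returned unchanged: the formula is
  0/0 there and identity is the least surprising degenerate behaviour.
  The mapping is monotone and idempotent up to binning (≤ 2/nbins).
* **clahe** — tile grid (default 8×8; edge tiles may be smaller), per-tile
  histogram clipped at `clip_limit` × mean bin height (default 2.0) with
  the excess redistributed uniformly in one pass, per-tile equalisation
  mapping as above, and bilinear blending of the four surrounding tile
  mappings via hat weights over tile centres (flat extension beyond the
  outermost centres).  One unclipped tile reduces exactly to global
  equalisation; a tile whose histogram occupies a single bin maps by
  identity, so constant regions pass through.
* **compress_histogram** — percentile-clip dynamic-range compression:
  stretch the `[low, high]` percentile band (default 2/98) to `[0, 1]`.
  This interpretation of "histogram compression" is a documented design
  choice; it discards exposure outliers (collimator edges, markers) before
  unsharp masking and illumination estimation.
* **unsharp_mask** — Gaussian blur at `sigma` (default 2 px), kernel
  truncated at radius `ceil(3σ)`, residual added back scaled by `amount`
  (default 1).
* **lime_enhance** — low-illumination enhancement for a single channel.
  Initial illumination estimate `t̂ = max(img, ε)` (for one channel the
  channel-max of the colour formulation is the image itself).  The refined
  map solves the sparse SPD system
  `(I + α Σ_{d∈{h,v}} D_dᵀ diag(w_d) D_d) t = t̂`, with forward-difference
  operators `D_d` (zero difference at the far boundary) and edge-aware
  weights `w_d = 1/(|D_d t̂| + ε)` — a first-order approximation that
  derives weights from `t̂` once, with no re-weighting iterations.  Defaults
  `α = 0.15`, `γ = 0.8`, `ε = 10⁻³`.  The system is solved by a sparse
  direct factorisation; the contract is the relative residual (≤ 10⁻⁸),
  not the algorithm.  Output `clip(img / clip(t, ε, 1)^γ, 0, 1)` never
  darkens the input when `γ ≤ 1`.  On a constant image `c` the closed form
  gives `c^{1−γ}` (only `γ = 1` maps to 1 exactly).

## Pipelines

* **Pr-1** (contrast-centred): `hist_equalize(sharpen(img))`, replicated
  into three identical channels.  Sharpening runs first so that the
  equalised histogram is the final one; running it after equalisation
  would re-distort the flattened histogram.
* **Pr-2** (edge-centred): channel 0 = `sharpen(img)`; channel 1 =
  `clahe(sharpen(img))`; channel 2 =
  `lime(unsharp(compress_histogram(img)))`, composing the operators in
  that order.  The three channels are pairwise distinct on any
  non-constant input.
* Pipelines are deterministic and run once per image, before augmentation
  in the training loop (augment-on-preprocessed): preprocessing is
  cacheable per image, whereas the augmentation draw changes every epoch.

## Augmentation policy

Each spec names an augmentation, an application chance `C ∈ [0, 1]`, and a
magnitude.  Magnitudes are *maxima*: a translation magnitude of 0.10 means
integer shifts drawn uniformly in ±10 % of each image extent, a rotation
magnitude of 20 means angles uniform in ±20°, matching standard randomised
augmentation practice.  Geometric fills are 0 (black), like the collimated
border of a radiograph.  Occlusion zeroes one rectangle of the requested
area with aspect ratio drawn in [0.5, 2]; noise is additive Gaussian
(default σ = 0.05 on the unit scale — the amplitude is a package choice, as
is the Gaussian model).  Rotations by exact multiples of 90° are performed
as grid rotations so the flip/rotation group identities hold exactly;
other angles use bilinear resampling.

One policy draw produces an explicit plan (gate outcomes plus drawn
magnitudes) that can be applied identically to every plane of a
three-channel stack and logged to an audit record.  Everything derives
from the policy seed: two runs with the same seed are identical.

## Phantom generator

The generator emulates what makes neonatal AXRs hard: a low-contrast
grayscale scene — dark background (0.05), bright body ellipse (0.55) with
±2 % pose jitter, brighter spine column (0.75), faint rib shading, 6–10
elliptical bowel-gas lucencies (−0.15) — plus class-specific lesions:

* **mNEC**: 3–6 clusters of small mottled lucencies (dots of radius
  0.8–2 % of the image side) at intensity −0.3 × `lesion_contrast`;
* **sNEC**: one large lucent crescent (disc minus shifted disc) in the
  upper abdomen at −0.4 × `lesion_contrast`.

The scene is blurred (σ = 1.5 px system blur), then white Gaussian noise
(default σ = 0.05) is added and the result clipped.  Scene, lesions and
noise come from three separate child streams of the per-image seed, so at
`lesion_contrast = 0` a pathological phantom is bit-identical to the NP
phantom of the same seed, and the only difference between classes is the
lesion content.  Ground-truth lesion masks are returned unblurred so
enhancement can be scored without a classifier.

Defaults (224×224, contrast 0.35, noise 0.05) are the desk-scale study
conditions used throughout the tests.  The sNEC crescent is placed fully
inside the body ellipse; the generator amplitudes were calibrated once so
that a logistic probe on intensity features reaches > 90 % five-fold
accuracy at contrast 0.8 / noise 0.02, then frozen.

The phantoms are stylised, not anatomically realistic.  In particular the
noise is *white*; real detector noise is weaker and spatially correlated.
Passing tests therefore demonstrate that the operators and the training
protocol behave as specified under controllable conditions — not that the
pipelines improve real clinical images.

### Lesion conspicuity metric

`lesion_contrast_metric` is a contrast-to-noise score:
`|mean(img[mask]) − mean(img[ring])| / (sd(img[ring]) + 10⁻⁶)` with the
ring the 5-pixel dilation of the mask minus the mask.  It is non-negative
and invariant under intensity inversion.

### Linear separability probe

`intensity_features` summarises an image by global mean/spread/quantiles
plus, when an oracle mask is supplied, image statistics over the lesion
region (ring-minus-lesion intensity deficit, CNR score, within-region sd).
Mask geometry itself (area, position) is deliberately excluded: it would
identify the class even at zero lesion amplitude, and the probe is meant
to track lesion *visibility*.  A logistic regression on these features
reaches ≈ 92 % five-fold accuracy at contrast 0.8 / noise 0.02 and is
monotone in lesion contrast.

## Cross-validation harness

Label-stratified k-fold splitting (default k = 5, an 80/20 rotation);
per-label fold counts differ by at most one.  Metrics: accuracy plus
macro-averaged precision, recall, F1, with 0 substituted for undefined
per-class ratios.  Macro averaging is the stricter convention and, with
balanced classes, nearly coincides with weighted averaging.  Run
comparison reports the mean-accuracy delta and a two-sided Welch t-test
over per-fold accuracies; sample variances are floored at 10⁻¹² so
zero-variance fold vectors still produce a defined p-value (identical
runs compare at p = 1).

The desk-scale backbone is a four-conv-block CNN (3×3 conv + ReLU + 2×2
max-pool; 8/16/32/32 filters) with a flattened linear softmax head,
implemented in numpy (channels-last im2col) and trained with Adam at
learning rate 10⁻³ and batch size 16 — the optimiser settings of the
full-scale protocol.  The flattened head (rather than global average
pooling) is essential here: the class-discriminating features are small
and localised, and pooling them away leaves no trainable signal.  Inputs
are the preprocessed stacks resized to 48×48; the augmentation policy is
re-drawn per image per epoch.  Default 50 epochs: the baseline arm reaches
≈ 1.0 training accuracy by epoch ≈ 30, and the augmented arm's validation
accuracy plateaus by ≈ 45, so both arms are compared after convergence —
the regime in which the full-scale protocol (150 epochs) operates, and the
only regime in which an augmentation-vs-baseline comparison is meaningful.
A `resnet50` backbone setting exists for full-scale replication but
requires torch to be installed.

Problem sizes in the tests (300 phantoms, 48×48 network inputs, 50
epochs, 3 harness seeds) are the package's desk-scale defaults, chosen so
the full study runs on a single CPU in minutes.

## Known limitations

* **Sharpening vs white noise.** The Laplacian sharpening kernel
  multiplies uncorrelated pixel noise by `‖k‖₂ = √29 ≈ 5.4` while leaving
  a lesion's mean offset unchanged.  Under the phantom's white-noise model
  the CNR of small mottled lesions on Pr-2's sharpen+CLAHE channel
  therefore usually *drops* relative to the raw image, even though CLAHE
  alone raises it for ≈ 95 % of phantoms.  On real radiographs, where
  noise is weaker and correlated by the detector, sharpening is far less
  destructive; this is a limitation of the phantom noise model, not of
  the pipeline composition, and is left visible in the test suite.
* Phantoms have no patient-level structure (one image per synthetic
  patient) and no physics (scatter, beam hardening).
* The numpy CNN is a desk-scale stand-in: it demonstrates protocol
  behaviour (seeding, fold rotation, augmentation interaction), not
  state-of-the-art classification.
* Multi-frame DICOM and colour radiographs are out of scope.
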