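# axr — enhancement, augmentation and evaluation for low-contrast abdominal radiographs

Necrotising enterocolitis (NEC) is a life-threatening intestinal disease of
premature neonates whose radiological signs on abdominal X-rays (AXRs) are
subtle: faint mottled intramural gas in medically managed disease (mNEC) and
lucent free-air patterns in surgical disease (sNEC), against a low-contrast
background.  Datasets are small because the disease is rare, so classifier
development leans heavily on two levers: stochastic **augmentation** (expand
the effective training set) and deterministic **preprocessing** (make the
subtle findings more visible before the network sees them).

This package implements both levers as a tested library and CLI, together
with a synthetic AXR phantom generator and a cross-validation harness, so
the whole methodology can be exercised end-to-end without any clinical data.

## What is inside

* `axr.image` — grayscale raster I/O (PNG / TIFF / DICOM), normalisation to
  `[0, 1]`, three-channel stacking.
* `axr.enhance` — the enhancement operators, each written from its
  mathematical definition:
  * `sharpen`: 3×3 kernel convolution (default Laplacian sharpen
    `[[0,−1,0],[−1,5,−1],[0,−1,0]]`),
  * `hist_equalize`: global histogram equalisation
    `v ↦ (cdf(v) − cdf_min) / (1 − cdf_min)`,
  * `clahe`: contrast-limited adaptive histogram equalisation with
    per-tile clipped histograms and bilinear blending of tile mappings,
  * `compress_histogram`: percentile-clip dynamic-range compression,
  * `unsharp_mask`: `img + amount · (img − G_σ * img)`,
  * `lime_enhance`: low-illumination enhancement — solve
    `(I + α Σ_d D_dᵀ W_d D_d) t = t̂` for a refined illumination map `t`,
    then output `img / clip(t, ε, 1)^γ`,
  * `invert`: photographic negative.
* `axr.pipelines` — the two composed preprocessing pipelines:
  * **Pr-1** (contrast-centred): `equalize(sharpen(img))`, replicated into
    three channels;
  * **Pr-2** (edge-centred): channel 0 `sharpen`, channel 1
    `clahe(sharpen)`, channel 2 `lime(unsharp(compress))`.
* `axr.augment` — seedable augmentation policies: translation, cropping,
  rotation, flips, occlusion, Gaussian noise, equalisation, sharpening,
  inversion, each applied with a per-draw chance *C* and a drawn magnitude.
* `axr.phantom` — three-class AXR phantoms (NP / mNEC / sNEC) with ground
  truth lesion masks and a tunable lesion-contrast knob.
* `axr.harness` — stratified k-fold cross-validation with a small numpy CNN
  trained by Adam, macro-averaged metrics, and Welch-t run comparison.

## Worked example

```python
from axr.enhance import clahe
from axr.phantom import PhantomSpec, generate_phantom, lesion_contrast_metric
from axr.pipelines import pr2

img, mask = generate_phantom(PhantomSpec(label="mNEC", lesion_contrast=0.35, seed=7))
raw = lesion_contrast_metric(img, mask)
clahe_only = lesion_contrast_metric(clahe(img), mask)
channel1 = lesion_contrast_metric(pr2(img)[1], mask)
print(f"lesion CNR: raw {raw:.2f} | CLAHE alone {clahe_only:.2f} | sharpen+CLAHE {channel1:.2f}")
```

prints

```
lesion CNR: raw 0.40 | CLAHE alone 0.64 | sharpen+CLAHE 0.23
```

CLAHE on its own raises the lesion's contrast-to-noise ratio against its
local background ring (it does so on ≈ 95 % of phantoms at these
settings), but the sharpening kernel that precedes it in Pr-2's second
channel amplifies the phantom's white pixel noise faster than the lesion
offset, so the composed channel scores lower here — see
`docs/methods.md`, "Known limitations", for why this is a property of the
phantom noise model rather than of the pipeline on real radiographs.

From the shell:

```
axr phantom --n-per-class 20 --seed 0 --contrast 0.35 --out data/
axr preprocess --pipeline pr2 --in data/mNEC_00020.png --out out.tiff
axr crossval --manifest data/manifest.csv --config cfg.yaml --out report/
```

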