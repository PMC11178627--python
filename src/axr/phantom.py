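"""Seedable abdominal-radiograph phantoms in three classes.

The generator emulates the appearance that makes neonatal bowel
radiographs hard to classify: a low-contrast grayscale scene with a
bright body ellipse, a brighter spine column, faint rib shading, and
scattered bowel-gas lucencies, degraded by system blur and noise.  On
top of this common scene, class-specific lesions are drawn:

* ``NP`` (no pathology) — nothing;
* ``mNEC`` (medically managed disease) — a few clusters of small mottled
  lucencies inside the bowel region, mimicking intramural gas;
* ``sNEC`` (surgically managed disease) — one large sub-diaphragmatic
  lucent crescent, mimicking free air.

Lesion amplitude is controlled by a single ``lesion_contrast`` knob so
the difficulty of the classification task is tunable, and ground-truth
lesion masks are returned so enhancement can be scored without any
classifier.  Phantoms are stylised, not anatomically realistic: the
contract is controllable class structure and subtlety.

The scene, the lesions, and the noise are drawn from three separate
seeded streams, so the only difference between classes at a given seed
is the lesion content itself.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .image import validate_gray, write_image

__all__ = [
    "LABELS",
    "PhantomSpec",
    "generate_phantom",
    "generate_dataset",
    "lesion_contrast_metric",
]

LABELS = ("NP", "mNEC", "sNEC")

# scene intensities (before blur/noise)
_BACKGROUND = 0.05
_BODY = 0.55
_SPINE = 0.75
_RIB = 0.05  # additive shading
_BOWEL_GAS = 0.15  # subtractive lucency
_MNEC_AMPLITUDE = 0.3  # scaled by lesion_contrast
_SNEC_AMPLITUDE = 0.4


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic radiograph.

    ``lesion_contrast`` in [0, 1] scales the intensity offset of the
    class-specific features relative to their surroundings (0 makes the
    pathological classes pixel-identical to NP at the same seed);
    ``noise_sigma`` is the additive Gaussian noise level on the [0, 1]
    scale and ``blur_sigma`` the system blur in pixels.
    """

    label: str = "NP"
    height: int = 224
    width: int = 224
    lesion_contrast: float = 0.35
    noise_sigma: float = 0.05
    blur_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if not 0.0 <= self.lesion_contrast <= 1.0:
            raise ValueError("lesion_contrast must lie in [0, 1]")
        if not 0.0 <= self.noise_sigma <= 1.0:
            raise ValueError("noise_sigma must lie in [0, 1]")
        if self.blur_sigma <= 0:
            raise ValueError("blur_sigma must be positive")
        if self.height < 8 or self.width < 8:
            raise ValueError("phantom must be at least 8x8")


def _ellipse_mask(
    shape: tuple[int, int], cy: float, cx: float, ry: float, rx: float
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0


def _sample_inside(
    rng: np.random.Generator, region: np.ndarray, n_tries: int = 200
) -> tuple[int, int]:
    """Rejection-sample a (row, col) inside a boolean region."""
    h, w = region.shape
    for _ in range(n_tries):
        r = int(rng.integers(0, h))
        c = int(rng.integers(0, w))
        if region[r, c]:
            return r, c
    rows, cols = np.nonzero(region)
    k = int(rng.integers(0, rows.size))
    return int(rows[k]), int(cols[k])


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one phantom; returns ``(image, lesion_mask)``.

    Deterministic per spec.  The lesion mask marks the class-specific
    pixels (all zeros for NP) and is not blurred.
    """
    h, w = spec.height, spec.width
    scale = min(h, w)
    scene_rng = np.random.default_rng([spec.seed, 0])
    lesion_rng = np.random.default_rng([spec.seed, 1])
    noise_rng = np.random.default_rng([spec.seed, 2])

    scene = np.full((h, w), _BACKGROUND)

    # body ellipse with mild pose jitter
    cy = h * (0.52 + scene_rng.uniform(-0.02, 0.02))
    cx = w * (0.50 + scene_rng.uniform(-0.02, 0.02))
    ry = h * 0.42 * (1 + scene_rng.uniform(-0.05, 0.05))
    rx = w * 0.34 * (1 + scene_rng.uniform(-0.05, 0.05))
    body = _ellipse_mask((h, w), cy, cx, ry, rx)
    scene[body] = _BODY

    # spine: bright vertical column through the body
    spine_cx = cx + w * scene_rng.uniform(-0.01, 0.01)
    half_width = max(1.0, w * 0.03)
    cols = np.arange(w)
    spine = (np.abs(cols[None, :] - spine_cx) <= half_width) & body
    scene[spine] = _SPINE

    # rib shading: faint horizontal bands over the upper body
    n_ribs = int(scene_rng.integers(3, 6))
    rows = np.arange(h)
    for i in range(n_ribs):
        band_c = cy - ry * (0.45 + 0.12 * i) + scene_rng.uniform(-1, 1)
        band = (np.abs(rows[:, None] - band_c) <= max(1.0, 0.008 * h)) & body
        scene[band] += _RIB

    # bowel-gas lucencies scattered in the abdomen, off the spine
    bowel_region = body & ~spine
    n_gas = int(scene_rng.integers(6, 11))
    for _ in range(n_gas):
        gy, gx = _sample_inside(scene_rng, bowel_region)
        gry = scale * scene_rng.uniform(0.04, 0.09)
        grx = scale * scene_rng.uniform(0.04, 0.09)
        gas = _ellipse_mask((h, w), gy, gx, gry, grx) & body
        scene[gas] -= _BOWEL_GAS

    # class-specific lesions (geometry from the dedicated lesion stream)
    lesion_mask = np.zeros((h, w), dtype=bool)
    if spec.label == "mNEC":
        n_clusters = int(lesion_rng.integers(3, 7))
        for _ in range(n_clusters):
            ly, lx = _sample_inside(lesion_rng, bowel_region)
            n_dots = int(lesion_rng.integers(4, 9))
            for _ in range(n_dots):
                dy = ly + lesion_rng.normal(0, 0.03 * scale)
                dx = lx + lesion_rng.normal(0, 0.03 * scale)
                r = scale * lesion_rng.uniform(0.008, 0.02)
                lesion_mask |= _ellipse_mask((h, w), dy, dx, r, r)
        lesion_mask &= bowel_region
        scene[lesion_mask] -= spec.lesion_contrast * _MNEC_AMPLITUDE
    elif spec.label == "sNEC":
        # lucent crescent under the diaphragm: a disc minus a shifted disc
        ccy = cy - ry * lesion_rng.uniform(0.35, 0.5)
        ccx = cx + w * lesion_rng.uniform(-0.08, 0.08)
        radius = scale * lesion_rng.uniform(0.12, 0.17)
        outer = _ellipse_mask((h, w), ccy, ccx, radius, radius * 1.3)
        inner = _ellipse_mask(
            (h, w), ccy + 0.45 * radius, ccx, radius, radius * 1.3
        )
        lesion_mask = outer & ~inner & body
        scene[lesion_mask] -= spec.lesion_contrast * _SNEC_AMPLITUDE

    scene = ndi.gaussian_filter(np.clip(scene, 0.0, 1.0), spec.blur_sigma)
    scene += noise_rng.normal(0.0, spec.noise_sigma, size=scene.shape)
    return np.clip(scene, 0.0, 1.0), lesion_mask


def generate_dataset(
    n_per_class: int,
    base_seed: int,
    out_dir: str | Path,
    template: PhantomSpec | None = None,
) -> pd.DataFrame:
    """Write a balanced phantom dataset and its manifest.

    Generates ``3 * n_per_class`` PNG images (per-image seeds
    ``base_seed + index``) plus lesion-mask PNGs for the pathological
    classes, and a ``manifest.csv`` with columns
    ``path,label,seed,lesion_contrast,mask_path``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be at least 1")
    template = template or PhantomSpec()
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc
    rows = []
    index = 0
    for label in LABELS:
        for _ in range(n_per_class):
            spec = replace(template, label=label, seed=base_seed + index)
            img, mask = generate_phantom(spec)
            img_path = out_dir / f"{label}_{index:05d}.png"
            write_image(img, img_path, bit_depth=16)
            mask_path = ""
            if label != "NP":
                mask_file = out_dir / f"{label}_{index:05d}_mask.png"
                write_image(mask.astype(np.float64), mask_file, bit_depth=8)
                mask_path = mask_file.name
            rows.append(
                {
                    "path": img_path.name,
                    "label": label,
                    "seed": spec.seed,
                    "lesion_contrast": spec.lesion_contrast,
                    "mask_path": mask_path,
                }
            )
            index += 1
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def lesion_contrast_metric(img: np.ndarray, mask: np.ndarray) -> float:
    """Contrast-to-noise-style lesion conspicuity score.

    ``|mean(lesion) - mean(ring)| / (sd(ring) + 1e-6)`` where the ring is
    the 5-pixel dilation of the lesion mask minus the mask itself.  The
    absolute value makes the score invariant under intensity inversion.
    """
    arr = validate_gray(img)
    m = np.asarray(mask, dtype=bool)
    if m.shape != arr.shape:
        raise ValueError("mask shape must match the image")
    if not m.any():
        raise ValueError("empty lesion mask (no-pathology input has no lesion)")
    ring = ndi.binary_dilation(m, iterations=5) & ~m
    if not ring.any():
        raise ValueError("lesion mask leaves no background ring")
    return float(
        abs(arr[m].mean() - arr[ring].mean()) / (arr[ring].std() + 1e-6)
    )
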