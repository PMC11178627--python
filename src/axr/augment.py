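"""Stochastic training-time augmentations with per-draw application chance.

Each augmentation has a deterministic core (``translate``, ``rotate``,
``crop_resize``, ``flip``, ``occlude_rect``, ...) and a seedable random
wrapper that draws its magnitude.  A policy is an ordered list of
augmentation specs; on every draw, each spec is applied independently
with its stated chance C, and magnitudes are sampled up to the stated
maximum — the convention of randomised augmentation pipelines, where a
table entry like "10% L" is the largest allowed shift, not a fixed one.

Geometric fills use 0 (black), matching the collimated black border of
radiographs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.transform import resize as _sk_resize

from .enhance import DEFAULT_SHARPEN_KERNEL, hist_equalize, invert, sharpen
from .image import validate_gray

__all__ = [
    "AugmentSpec",
    "AugmentPolicy",
    "PolicyError",
    "translate",
    "crop_resize",
    "rotate",
    "flip",
    "occlude_rect",
    "random_translate",
    "random_crop_resize",
    "random_rotate",
    "random_occlude",
    "random_noise",
    "apply_policy",
    "apply_policy_stack",
]

AUGMENT_NAMES = (
    "translation",
    "cropping",
    "rotation",
    "hflip",
    "vflip",
    "occlusion",
    "noise",
    "equalisation",
    "sharpening",
    "inversion",
)


class PolicyError(ValueError):
    """Raised for malformed augmentation policies."""


@dataclass(frozen=True)
class AugmentSpec:
    """One augmentation: its name, application chance C, and magnitude.

    Magnitude semantics by name: translation — max shift as a fraction of
    the image length; cropping — crop window side in pixels; rotation —
    max angle in degrees; occlusion — occluded fraction of image area;
    noise — Gaussian sigma on the [0, 1] scale.  The purely photometric
    augmentations (equalisation, sharpening, inversion, flips) take no
    magnitude.
    """

    name: str
    chance: float = 1.0
    magnitude: float | None = None

    def __post_init__(self) -> None:
        if self.name not in AUGMENT_NAMES:
            raise PolicyError(f"unknown augmentation {self.name!r}")
        if not 0.0 <= self.chance <= 1.0:
            raise PolicyError(f"chance must lie in [0, 1], got {self.chance}")


@dataclass(frozen=True)
class AugmentPolicy:
    """Ordered augmentation specs plus the seed of their random stream."""

    specs: tuple[AugmentSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "specs", tuple(self.specs))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# deterministic cores


def translate(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Shift by whole pixels; vacated pixels are filled with 0."""
    arr = validate_gray(img)
    h, w = arr.shape
    out = np.zeros_like(arr)
    ys = slice(max(dy, 0), min(h, h + dy))
    xs = slice(max(dx, 0), min(w, w + dx))
    ys_src = slice(max(-dy, 0), min(h, h - dy))
    xs_src = slice(max(-dx, 0), min(w, w - dx))
    out[ys, xs] = arr[ys_src, xs_src]
    return out


def crop_resize(img: np.ndarray, top: int, left: int, crop_size: int) -> np.ndarray:
    """Extract a square window and resize it back to the original frame."""
    arr = validate_gray(img)
    h, w = arr.shape
    if crop_size > min(h, w):
        raise ValueError(f"crop_size {crop_size} exceeds image extent {min(h, w)}")
    if not (0 <= top <= h - crop_size and 0 <= left <= w - crop_size):
        raise ValueError("crop window out of frame")
    window = arr[top : top + crop_size, left : left + crop_size]
    if window.shape == arr.shape:
        return window.copy()
    out = _sk_resize(window, arr.shape, order=1, mode="edge", anti_aliasing=False)
    return np.clip(out, 0.0, 1.0)


def rotate(img: np.ndarray, angle_deg: float, order: int = 1) -> np.ndarray:
    """Rotate about the image centre, same output shape, black fill.

    Angles that are exact multiples of 90 degrees are grid rotations and
    are performed exactly (no resampling error); other angles use spline
    interpolation of the given order.
    """
    arr = validate_gray(img)
    if angle_deg % 90 == 0:
        k = int(angle_deg // 90) % 4
        if k == 0:
            return arr.copy()
        if arr.shape[0] == arr.shape[1] or k == 2:
            return np.rot90(arr, k).copy()
    out = ndi.rotate(
        arr, angle_deg, reshape=False, order=order, mode="constant", cval=0.0
    )
    return np.clip(out, 0.0, 1.0)


def flip(img: np.ndarray, axis: str) -> np.ndarray:
    """Reverse column order (``"horizontal"``) or row order (``"vertical"``)."""
    arr = validate_gray(img)
    if axis == "horizontal":
        return arr[:, ::-1].copy()
    if axis == "vertical":
        return arr[::-1, :].copy()
    raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")


def occlude_rect(img: np.ndarray, top: int, left: int, height: int, width: int) -> np.ndarray:
    """Zero out one axis-aligned rectangle; the complement is untouched."""
    arr = validate_gray(img).copy()
    arr[top : top + height, left : left + width] = 0.0
    return arr


# ---------------------------------------------------------------------------
# random wrappers


def random_translate(
    img: np.ndarray, max_frac: float, rng: np.random.Generator
) -> np.ndarray:
    """Shift by uniform integer offsets up to ``max_frac`` of each extent."""
    if not 0.0 <= max_frac <= 0.5:
        raise ValueError("max_frac must lie in [0, 0.5]")
    arr = validate_gray(img)
    h, w = arr.shape
    my, mx = round(max_frac * h), round(max_frac * w)
    dy = int(rng.integers(-my, my + 1))
    dx = int(rng.integers(-mx, mx + 1))
    return translate(arr, dy, dx)


def random_crop_resize(
    img: np.ndarray, crop_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Crop a random square window and resize back to the full frame."""
    arr = validate_gray(img)
    h, w = arr.shape
    if crop_size > min(h, w):
        raise ValueError(f"crop_size {crop_size} exceeds image extent {min(h, w)}")
    top = int(rng.integers(0, h - crop_size + 1))
    left = int(rng.integers(0, w - crop_size + 1))
    return crop_resize(arr, top, left, crop_size)


def random_rotate(
    img: np.ndarray, max_deg: float, rng: np.random.Generator
) -> np.ndarray:
    """Rotate by an angle drawn uniformly from [-max_deg, +max_deg]."""
    angle = float(rng.uniform(-max_deg, max_deg))
    return rotate(img, angle)


def random_occlude(
    img: np.ndarray, area_frac: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero a random rectangle covering ``area_frac`` of the image area.

    The aspect ratio is drawn uniformly from [0.5, 2] and the rectangle
    is clipped to the frame, so the realised area matches the request up
    to rounding.
    """
    if not 0.0 < area_frac < 1.0:
        raise ValueError("area_frac must lie in (0, 1)")
    arr = validate_gray(img)
    h, w = arr.shape
    area = round(area_frac * h * w)
    aspect = float(rng.uniform(0.5, 2.0))
    rect_h = int(np.clip(round(np.sqrt(area * aspect)), 1, h))
    rect_w = int(np.clip(round(area / rect_h), 1, w))
    top = int(rng.integers(0, h - rect_h + 1))
    left = int(rng.integers(0, w - rect_w + 1))
    return occlude_rect(arr, top, left, rect_h, rect_w)


def random_noise(img: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise and clip back to [0, 1]."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    arr = validate_gray(img)
    return np.clip(arr + rng.normal(0.0, sigma, size=arr.shape), 0.0, 1.0)


# ---------------------------------------------------------------------------
# policy application

_DEFAULTS = {
    "translation": 0.10,  # max shift fraction
    "rotation": 20.0,  # max degrees
    "occlusion": 0.05,  # area fraction
    "noise": 0.05,  # Gaussian sigma on [0, 1]
}


def _draw_plan(
    shape: tuple[int, int],
    policy: AugmentPolicy,
    rng: np.random.Generator,
    audit: list[dict] | None = None,
) -> list[tuple[str, dict]]:
    """Draw the chance gates and magnitudes for one pass of the policy.

    Returning an explicit plan keeps the random draws independent of how
    many channels the plan is later applied to, so a three-channel stack
    receives the same geometric transform on every plane.
    """
    h, w = shape
    plan: list[tuple[str, dict]] = []
    for i, spec in enumerate(policy.specs):
        gate = float(rng.uniform())
        applied = gate < spec.chance
        kwargs: dict = {}
        if applied:
            mag = spec.magnitude
            if spec.name == "translation":
                frac = _DEFAULTS["translation"] if mag is None else float(mag)
                my, mx = round(frac * h), round(frac * w)
                kwargs = {
                    "dy": int(rng.integers(-my, my + 1)),
                    "dx": int(rng.integers(-mx, mx + 1)),
                }
            elif spec.name == "cropping":
                if mag is None:
                    raise PolicyError("cropping requires a crop_size magnitude")
                size = int(mag)
                if size > min(h, w):
                    raise PolicyError(
                        f"crop_size {size} exceeds image extent {min(h, w)}"
                    )
                kwargs = {
                    "top": int(rng.integers(0, h - size + 1)),
                    "left": int(rng.integers(0, w - size + 1)),
                    "crop_size": size,
                }
            elif spec.name == "rotation":
                max_deg = _DEFAULTS["rotation"] if mag is None else float(mag)
                kwargs = {"angle_deg": float(rng.uniform(-max_deg, max_deg))}
            elif spec.name == "occlusion":
                frac = _DEFAULTS["occlusion"] if mag is None else float(mag)
                area = round(frac * h * w)
                aspect = float(rng.uniform(0.5, 2.0))
                rect_h = int(np.clip(round(np.sqrt(area * aspect)), 1, h))
                rect_w = int(np.clip(round(area / rect_h), 1, w))
                kwargs = {
                    "top": int(rng.integers(0, h - rect_h + 1)),
                    "left": int(rng.integers(0, w - rect_w + 1)),
                    "height": rect_h,
                    "width": rect_w,
                }
            elif spec.name == "noise":
                sigma = _DEFAULTS["noise"] if mag is None else float(mag)
                # pre-draw the noise seed so channel count cannot desync draws
                kwargs = {"sigma": sigma, "seed": int(rng.integers(0, 2**31))}
            plan.append((spec.name, kwargs))
        if audit is not None:
            audit.append(
                {"index": i, "name": spec.name, "applied": applied, **kwargs}
            )
    return plan


def _apply_plan_gray(img: np.ndarray, plan: list[tuple[str, dict]]) -> np.ndarray:
    out = img
    for name, kwargs in plan:
        if name == "translation":
            out = translate(out, **kwargs)
        elif name == "cropping":
            out = crop_resize(out, **kwargs)
        elif name == "rotation":
            out = rotate(out, kwargs["angle_deg"])
        elif name == "hflip":
            out = flip(out, "horizontal")
        elif name == "vflip":
            out = flip(out, "vertical")
        elif name == "occlusion":
            out = occlude_rect(out, **kwargs)
        elif name == "noise":
            noise_rng = np.random.default_rng(kwargs["seed"])
            out = random_noise(out, kwargs["sigma"], noise_rng)
        elif name == "equalisation":
            out = hist_equalize(out)
        elif name == "sharpening":
            out = sharpen(out, DEFAULT_SHARPEN_KERNEL)
        elif name == "inversion":
            out = invert(out)
    return out


def apply_policy(
    img: np.ndarray,
    policy: AugmentPolicy,
    rng: np.random.Generator | None = None,
    audit: list[dict] | None = None,
) -> np.ndarray:
    """Apply each spec in order, gated by an independent uniform draw.

    Fully reproducible: with the same image, policy seed and draw
    position the output is identical.  ``audit``, if given, receives one
    record per spec with the gate outcome and drawn magnitudes.
    """
    arr = validate_gray(img)
    stream = policy.rng() if rng is None else rng
    plan = _draw_plan(arr.shape, policy, stream, audit)
    return _apply_plan_gray(arr, plan)


def apply_policy_stack(
    stack: np.ndarray,
    policy: AugmentPolicy,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Apply one policy draw identically to every plane of a (C, H, W) stack."""
    arr = np.asarray(stack, dtype=np.float64)
    stream = policy.rng() if rng is None else rng
    plan = _draw_plan(arr.shape[-2:], policy, stream)
    return np.stack([_apply_plan_gray(ch, plan) for ch in arr])
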