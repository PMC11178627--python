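"""Canonical grayscale image representation and raster I/O.

Every operator in this package works on a single convention: a 2-D
``float64`` array of intensities in ``[0, 1]``, row-major, origin at the
top-left, ``(row, col)`` indexed.  Brighter soft tissue has higher value.
Three-channel stacks (the classifier input format) are ``(3, H, W)``
arrays whose planes individually obey the same convention.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "MIN_SIZE",
    "read_gray_image",
    "write_image",
    "to_three_channel",
    "validate_gray",
    "validate_stack",
]

#: Operators assume non-degenerate rasters of at least this many rows/cols.
MIN_SIZE = 8

_DICOM_SUFFIXES = {".dcm", ".dicom"}


def validate_gray(img: np.ndarray) -> np.ndarray:
    """Check the grayscale invariants and return the array as float64.

    Raises ``ValueError`` if the array is not 2-D, smaller than
    ``MIN_SIZE`` in either dimension, non-finite, or outside ``[0, 1]``.
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale array, got shape {arr.shape}")
    if arr.shape[0] < MIN_SIZE or arr.shape[1] < MIN_SIZE:
        raise ValueError(
            f"image {arr.shape} smaller than the minimum raster {MIN_SIZE}x{MIN_SIZE}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("image intensities must lie in [0, 1]")
    return arr


def validate_stack(stack: np.ndarray) -> np.ndarray:
    """Check the three-channel invariants: shape (3, H, W), planes valid."""
    arr = np.asarray(stack, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[0] != 3:
        raise ValueError(f"expected a (3, H, W) stack, got shape {arr.shape}")
    for ch in arr:
        validate_gray(ch)
    return arr


def to_three_channel(img: np.ndarray) -> np.ndarray:
    """Replicate a grayscale image into a (3, H, W) stack.

    Classifier backbones expect three input planes; replication is the
    neutral conversion used by the baseline pipeline.
    """
    arr = validate_gray(img)
    return np.stack([arr, arr, arr])


def _normalise_integer(arr: np.ndarray) -> np.ndarray:
    """Rescale an integer raster by the full range of its container depth.

    Using the representable range (not the observed min/max) keeps
    identical scenes at different exposures distinguishable.
    """
    info = np.iinfo(arr.dtype)
    lo, hi = float(info.min), float(info.max)
    return (arr.astype(np.float64) - lo) / (hi - lo)


def _read_dicom(path: Path) -> np.ndarray:
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(np.float64)
    if arr.ndim == 3:  # single-frame multi-sample: average the samples
        arr = arr.mean(axis=-1 if arr.shape[-1] in (3, 4) else 0)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    lo, hi = arr.min(), arr.max()
    if hi <= lo:
        warnings.warn(f"zero dynamic range in {path}; returning a constant 0 image")
        return np.zeros_like(arr)
    arr = (arr - lo) / (hi - lo)
    # MONOCHROME1 stores inverted video: low values are bright.
    if str(getattr(ds, "PhotometricInterpretation", "")).startswith("MONOCHROME1"):
        arr = 1.0 - arr
    return arr


def read_gray_image(path: str | Path) -> np.ndarray:
    """Read a PNG, TIFF, or DICOM raster as a [0, 1] grayscale array.

    Integer containers are rescaled by their full bit-depth range;
    DICOM applies rescale slope/intercept and then windows to the stored
    min/max.  Multi-channel sources are reduced by channel averaging.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read image: {path} does not exist")
    try:
        if path.suffix.lower() in _DICOM_SUFFIXES:
            arr = _read_dicom(path)
        else:
            raw = iio.imread(path)
            if np.issubdtype(raw.dtype, np.integer):
                arr = _normalise_integer(raw)
            else:
                arr = raw.astype(np.float64)
                if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
                    lo, hi = arr.min(), arr.max()
                    if hi <= lo:
                        warnings.warn(
                            f"zero dynamic range in {path}; returning a constant 0 image"
                        )
                        arr = np.zeros_like(arr)
                    else:
                        arr = (arr - lo) / (hi - lo)
            if arr.ndim == 3:
                arr = arr.mean(axis=-1)
    except (IOError, ValueError) as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    return validate_gray(np.clip(arr, 0.0, 1.0))


def write_image(img: np.ndarray, path: str | Path, bit_depth: int = 8) -> None:
    """Quantise to 8 or 16 bits and write a PNG/TIFF raster.

    Values are quantised by ``round(v * (2**bit_depth - 1))`` so a
    subsequent :func:`read_gray_image` recovers each intensity within
    ``1 / (2**bit_depth - 1)``.  A (3, H, W) stack is written as a
    three-plane (H, W, 3) raster.
    """
    if bit_depth not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim == 3:
        arr = np.moveaxis(validate_stack(arr), 0, -1)
    else:
        arr = validate_gray(arr)
    path = Path(path)
    if arr.ndim == 3 and bit_depth == 16 and path.suffix.lower() == ".png":
        raise ValueError(
            "16-bit three-channel PNG is not supported; write a TIFF or use 8 bits"
        )
    scale = 2**bit_depth - 1
    quant = np.rint(arr * scale).astype(np.uint8 if bit_depth == 8 else np.uint16)
    try:
        iio.imwrite(path, quant)
    except (IOError, OSError, ValueError) as exc:
        raise IOError(f"cannot write image {path}: {exc}") from exc
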