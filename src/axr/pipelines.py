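"""The two preprocessing pipelines and the neutral baseline.

Pr-1 (contrast-centred): sharpen, then globally equalise, replicated
into three identical channels.  Sharpening runs first so equalisation's
output histogram is not re-distorted afterwards.

Pr-2 (edge-centred): three differently enhanced planes of the same
radiograph —

* channel 0: sharpening kernel only,
* channel 1: sharpening kernel followed by CLAHE,
* channel 2: percentile histogram compression, unsharp masking, then
  low-illumination enhancement (in that order).

Both pipelines are deterministic; the baseline simply replicates the
input into three channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .enhance import (
    DEFAULT_SHARPEN_KERNEL,
    ClaheParams,
    LimeParams,
    clahe,
    compress_histogram,
    hist_equalize,
    lime_enhance,
    sharpen,
    unsharp_mask,
)
from .image import to_three_channel, validate_gray

__all__ = ["PipelineConfig", "PIPELINE_NAMES", "pr1", "pr2", "run_pipeline"]

PIPELINE_NAMES = ("baseline", "pr1", "pr2")


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of the constituent enhancement operators."""

    sharpen_kernel: np.ndarray = field(
        default_factory=lambda: DEFAULT_SHARPEN_KERNEL.copy()
    )
    nbins: int = 256
    clahe: ClaheParams = field(default_factory=ClaheParams)
    compress_low_pct: float = 2.0
    compress_high_pct: float = 98.0
    unsharp_sigma: float = 2.0
    unsharp_amount: float = 1.0
    lime: LimeParams = field(default_factory=LimeParams)


def pr1(img: np.ndarray, cfg: PipelineConfig | None = None) -> np.ndarray:
    """Contrast-centred pipeline: equalise(sharpen(img)), replicated x3."""
    cfg = cfg or PipelineConfig()
    g = hist_equalize(sharpen(validate_gray(img), cfg.sharpen_kernel), cfg.nbins)
    return to_three_channel(g)


def pr2(img: np.ndarray, cfg: PipelineConfig | None = None) -> np.ndarray:
    """Edge-centred pipeline: three differently enhanced planes."""
    cfg = cfg or PipelineConfig()
    arr = validate_gray(img)
    sharp = sharpen(arr, cfg.sharpen_kernel)
    ch0 = sharp
    ch1 = clahe(sharp, cfg.clahe)
    ch2 = lime_enhance(
        unsharp_mask(
            compress_histogram(arr, cfg.compress_low_pct, cfg.compress_high_pct),
            cfg.unsharp_sigma,
            cfg.unsharp_amount,
        ),
        cfg.lime,
    )
    return np.stack([ch0, ch1, ch2])


def run_pipeline(
    name: str, img: np.ndarray, cfg: PipelineConfig | None = None
) -> np.ndarray:
    """Dispatch by pipeline name; ``baseline`` is pure replication."""
    if name == "baseline":
        return to_three_channel(img)
    if name == "pr1":
        return pr1(img, cfg)
    if name == "pr2":
        return pr2(img, cfg)
    raise ValueError(f"unknown pipeline {name!r}; expected one of {PIPELINE_NAMES}")
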