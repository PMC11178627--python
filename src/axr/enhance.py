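"""Deterministic enhancement operators for low-contrast radiographs.

These are the building blocks of the two preprocessing pipelines:

* ``sharpen`` — small-kernel convolution emphasising edges,
* ``hist_equalize`` / ``clahe`` — global and contrast-limited adaptive
  histogram equalisation,
* ``compress_histogram`` — percentile-clip dynamic-range compression,
* ``unsharp_mask`` — Gaussian-difference sharpening,
* ``lime_enhance`` — low-illumination enhancement by estimating and
  refining a per-pixel illumination map, then dividing it out,
* ``invert`` — photographic negative.

All operators map ``[0, 1]`` images to ``[0, 1]`` images and are
bit-deterministic.  Convolutions use reflective boundaries to avoid the
dark frame artefacts that equalisation would amplify.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .image import validate_gray

__all__ = [
    "DEFAULT_SHARPEN_KERNEL",
    "ClaheParams",
    "LimeParams",
    "SolverError",
    "sharpen",
    "hist_equalize",
    "clahe",
    "unsharp_mask",
    "compress_histogram",
    "lime_enhance",
    "invert",
]

#: Classic Laplacian-based sharpening kernel; entries sum to 1 so flat
#: regions are preserved.
DEFAULT_SHARPEN_KERNEL = np.array(
    [[0.0, -1.0, 0.0], [-1.0, 5.0, -1.0], [0.0, -1.0, 0.0]]
)


class SolverError(RuntimeError):
    """Raised when the illumination refinement solve fails to converge."""


@dataclass(frozen=True)
class ClaheParams:
    """Contrast-limited adaptive histogram equalisation settings.

    ``clip_limit`` is expressed relative to the uniform (mean) bin height
    of a tile histogram; ``None`` disables clipping entirely.
    """

    tiles_y: int = 8
    tiles_x: int = 8
    clip_limit: float | None = 2.0
    nbins: int = 256

    def __post_init__(self) -> None:
        if self.tiles_y < 1 or self.tiles_x < 1:
            raise ValueError("tile counts must be positive")
        if self.nbins < 16:
            raise ValueError("nbins must be at least 16")
        if self.clip_limit is not None and self.clip_limit <= 0:
            raise ValueError("clip_limit must be positive or None")


@dataclass(frozen=True)
class LimeParams:
    """Illumination-map refinement settings.

    alpha
        Weight of the edge-aware smoothness penalty on the refined
        illumination (0 disables refinement).
    gamma
        Gamma-correction exponent applied to the illumination map before
        division; values below 1 brighten dark regions more gently.
    epsilon
        Floor for gradients and illumination, preventing division blow-up.
    weight_strategy
        ``"inverse_gradient"`` (edge-aware, default) or ``"uniform"``.
    """

    alpha: float = 0.15
    gamma: float = 0.8
    epsilon: float = 1e-3
    weight_strategy: str = "inverse_gradient"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not 0 < self.epsilon < 0.1:
            raise ValueError("epsilon must lie in (0, 0.1)")
        if self.weight_strategy not in ("uniform", "inverse_gradient"):
            raise ValueError(f"unknown weight strategy {self.weight_strategy!r}")


def sharpen(img: np.ndarray, kernel: np.ndarray | None = None) -> np.ndarray:
    """Convolve with an intensity-preserving sharpening kernel and clip.

    The kernel must sum to 1 (within 1e-9) so constant regions pass
    through unchanged.  Boundaries are reflective.
    """
    arr = validate_gray(img)
    k = DEFAULT_SHARPEN_KERNEL if kernel is None else np.asarray(kernel, dtype=np.float64)
    if k.shape != (3, 3):
        raise ValueError(f"sharpening kernel must be 3x3, got {k.shape}")
    if abs(k.sum() - 1.0) > 1e-9:
        raise ValueError(f"sharpening kernel must sum to 1, got {k.sum()!r}")
    out = ndi.convolve(arr, k, mode="reflect")
    return np.clip(out, 0.0, 1.0)


def _bin_index(arr: np.ndarray, nbins: int) -> np.ndarray:
    idx = np.floor(arr * nbins).astype(np.intp)
    return np.clip(idx, 0, nbins - 1)


def _equalize_lut(hist: np.ndarray) -> np.ndarray | None:
    """Equalisation lookup table from a (possibly clipped) histogram.

    Maps bin b to ``(cdf(b) - cdf_min) / (1 - cdf_min)`` where cdf_min is
    the cdf at the lowest occupied bin.  Returns ``None`` (identity
    mapping on values) for the degenerate single-level histogram, so
    constant regions are left untouched.
    """
    total = hist.sum()
    occupied = np.nonzero(hist)[0]
    if total == 0 or occupied.size == 0:
        return None
    cdf = np.cumsum(hist) / total
    cdf_min = cdf[occupied[0]]
    denom = 1.0 - cdf_min
    if denom <= 1e-12:
        return None
    return np.clip((cdf - cdf_min) / denom, 0.0, 1.0)


def hist_equalize(img: np.ndarray, nbins: int = 256) -> np.ndarray:
    """Global histogram equalisation over ``nbins`` uniform bins.

    The mapping is a monotone non-decreasing function of intensity; a
    constant image is returned unchanged (the standard formula is 0/0
    there, and identity is the least surprising degenerate behaviour).
    """
    arr = validate_gray(img)
    if nbins < 2:
        raise ValueError("nbins must be at least 2")
    bins = _bin_index(arr, nbins)
    hist = np.bincount(bins.ravel(), minlength=nbins).astype(np.float64)
    lut = _equalize_lut(hist)
    if lut is None:
        return arr.copy()
    return lut[bins]


def _clip_histogram(hist: np.ndarray, clip_limit: float | None) -> np.ndarray:
    """Clip bins at ``clip_limit`` x mean height, redistribute the excess
    uniformly (single pass)."""
    if clip_limit is None:
        return hist
    limit = clip_limit * hist.sum() / hist.size
    excess = np.maximum(hist - limit, 0.0).sum()
    return np.minimum(hist, limit) + excess / hist.size


def _tile_centers(extent: int, ntiles: int) -> tuple[list[np.ndarray], np.ndarray]:
    """Split ``range(extent)`` into ``ntiles`` contiguous runs (edge runs
    may be shorter) and return the runs with their centre coordinates."""
    runs = np.array_split(np.arange(extent), ntiles)
    centers = np.array([float(r.mean()) for r in runs])
    return runs, centers


def _hat_weights(coords: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Per-tile bilinear hat functions over pixel coordinates.

    Row i holds tile i's weight at each coordinate: 1 at its centre,
    linear to 0 at the adjacent centres, constant 1 beyond the outermost
    centres.  Rows sum to 1 at every coordinate.
    """
    n = centers.size
    weights = np.zeros((n, coords.size))
    if n == 1:
        weights[0] = 1.0
        return weights
    for i in range(n):
        xp = [centers[max(i - 1, 0)], centers[i], centers[min(i + 1, n - 1)]]
        fp = [0.0, 1.0, 0.0]
        if i == 0:
            xp, fp = xp[1:], fp[1:]  # flat extension below the first centre
        if i == n - 1:
            xp, fp = xp[:-1], fp[:-1]
        weights[i] = np.interp(coords, xp, fp)
    return weights


def clahe(img: np.ndarray, params: ClaheParams | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalisation.

    The image is divided into a ``tiles_y x tiles_x`` grid; each tile gets
    its own clipped-histogram equalisation mapping, and every pixel is
    mapped by bilinear interpolation of the four surrounding tile
    mappings.  With a single unclipped tile this reduces to
    :func:`hist_equalize` exactly.
    """
    arr = validate_gray(img)
    p = params or ClaheParams()
    h, w = arr.shape
    if p.tiles_y > h or p.tiles_x > w:
        raise ValueError(
            f"tile grid {p.tiles_y}x{p.tiles_x} larger than image {h}x{w}"
        )
    row_runs, row_centers = _tile_centers(h, p.tiles_y)
    col_runs, col_centers = _tile_centers(w, p.tiles_x)
    bins = _bin_index(arr, p.nbins)

    luts: list[list[np.ndarray | None]] = []
    for rr in row_runs:
        row_luts: list[np.ndarray | None] = []
        for cc in col_runs:
            tile_bins = bins[np.ix_(rr, cc)]
            hist = np.bincount(tile_bins.ravel(), minlength=p.nbins).astype(np.float64)
            if np.count_nonzero(hist) <= 1:
                row_luts.append(None)  # constant tile: identity on values
            else:
                row_luts.append(_equalize_lut(_clip_histogram(hist, p.clip_limit)))
        luts.append(row_luts)

    if all(lut is None for row in luts for lut in row):
        return arr.copy()  # every tile degenerate: exact identity
    wrow = _hat_weights(np.arange(h, dtype=np.float64), row_centers)
    wcol = _hat_weights(np.arange(w, dtype=np.float64), col_centers)
    out = np.zeros_like(arr)
    for i in range(p.tiles_y):
        for j in range(p.tiles_x):
            weight = np.outer(wrow[i], wcol[j])
            if not weight.any():
                continue
            lut = luts[i][j]
            mapped = arr if lut is None else lut[bins]
            out += weight * mapped
    return np.clip(out, 0.0, 1.0)


def unsharp_mask(img: np.ndarray, sigma: float = 2.0, amount: float = 1.0) -> np.ndarray:
    """Sharpen by adding back the Gaussian high-pass residual.

    ``out = clip(img + amount * (img - blur(img, sigma)), 0, 1)`` with a
    reflective-boundary Gaussian truncated at radius ``ceil(3 * sigma)``.
    """
    arr = validate_gray(img)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if amount < 0:
        raise ValueError("amount must be non-negative")
    if amount == 0:
        return arr.copy()
    blurred = ndi.gaussian_filter(
        arr, sigma, mode="reflect", radius=math.ceil(3 * sigma)
    )
    return np.clip(arr + amount * (arr - blurred), 0.0, 1.0)


def compress_histogram(
    img: np.ndarray, low_pct: float = 2.0, high_pct: float = 98.0
) -> np.ndarray:
    """Percentile-clip dynamic-range compression.

    Stretches the ``[low_pct, high_pct]`` percentile band to the full
    ``[0, 1]`` range, clipping the tails.  Discards the extreme exposure
    outliers so the subsequent unsharp mask and illumination estimate are
    not dominated by collimator edges or markers.
    """
    arr = validate_gray(img)
    if not (0 <= low_pct < 50 and 50 < high_pct <= 100):
        raise ValueError("expected low_pct in [0, 50) and high_pct in (50, 100]")
    lo, hi = np.percentile(arr, [low_pct, high_pct])
    if hi <= lo:
        return arr.copy()
    return np.clip((arr - lo) / (hi - lo), 0.0, 1.0)


def _forward_diff_ops(h: int, w: int) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Sparse forward-difference operators (horizontal and vertical) on a
    flattened h*w grid, with reflective boundary (zero difference at the
    far edge)."""
    n = h * w
    idx = np.arange(n).reshape(h, w)

    rows = idx[:, :-1].ravel()
    dh = sp.coo_matrix(
        (
            np.concatenate([-np.ones(rows.size), np.ones(rows.size)]),
            (np.concatenate([rows, rows]), np.concatenate([rows, rows + 1])),
        ),
        shape=(n, n),
    ).tocsr()

    rows = idx[:-1, :].ravel()
    dv = sp.coo_matrix(
        (
            np.concatenate([-np.ones(rows.size), np.ones(rows.size)]),
            (np.concatenate([rows, rows]), np.concatenate([rows, rows + w])),
        ),
        shape=(n, n),
    ).tocsr()
    return dh, dv


def refine_illumination(
    t_hat: np.ndarray, params: LimeParams
) -> np.ndarray:
    """Solve the weighted-quadratic illumination refinement.

    Minimises ``||t - t_hat||^2 + alpha * sum_d ||W_d^(1/2) D_d t||^2``,
    i.e. solves the sparse SPD system
    ``(I + alpha * sum_d D_d' W_d D_d) t = t_hat``, where ``D_d`` are
    forward differences and ``W_d = 1 / (|D_d t_hat| + eps)`` under the
    edge-aware strategy (first-order approximation: weights come from the
    initial estimate only, no re-weighting iterations).
    """
    h, w = t_hat.shape
    if params.alpha == 0:
        return t_hat.copy()
    dh, dv = _forward_diff_ops(h, w)
    flat = t_hat.ravel()
    terms = []
    for d in (dh, dv):
        grad = d @ flat
        if params.weight_strategy == "inverse_gradient":
            weight = 1.0 / (np.abs(grad) + params.epsilon)
        else:
            weight = np.ones_like(grad)
        terms.append(d.T @ sp.diags(weight) @ d)
    system = (sp.identity(h * w, format="csr") + params.alpha * (terms[0] + terms[1])).tocsc()
    t = spla.spsolve(system, flat)
    residual = np.linalg.norm(system @ t - flat) / np.linalg.norm(flat)
    if not np.isfinite(residual) or residual > 1e-8:
        raise SolverError(
            f"illumination solve did not converge: relative residual {residual:.3e}"
        )
    return t.reshape(h, w)


def lime_enhance(img: np.ndarray, params: LimeParams | None = None) -> np.ndarray:
    """Low-illumination enhancement via a refined illumination map.

    For a single-channel image the initial illumination estimate is the
    image itself (floored at epsilon).  It is refined under an edge-aware
    smoothness penalty, gamma-corrected, and divided out:
    ``out = clip(img / clip(t, eps, 1)**gamma, 0, 1)``.  With gamma <= 1
    the map never exceeds 1, so the output never darkens the input.
    """
    arr = validate_gray(img)
    p = params or LimeParams()
    t_hat = np.maximum(arr, p.epsilon)
    t = refine_illumination(t_hat, p)
    illumination = np.clip(t, p.epsilon, 1.0) ** p.gamma
    return np.clip(arr / illumination, 0.0, 1.0)


def invert(img: np.ndarray) -> np.ndarray:
    """Photographic negative: ``1 - img``."""
    return 1.0 - validate_gray(img)
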