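"""Enhancement operators against brute-force oracles and their algebra."""

import math

import numpy as np
import pytest

from axr.enhance import (
    DEFAULT_SHARPEN_KERNEL,
    ClaheParams,
    LimeParams,
    clahe,
    compress_histogram,
    hist_equalize,
    invert,
    lime_enhance,
    refine_illumination,
    sharpen,
    unsharp_mask,
)
from conftest import random_images

# ---------------------------------------------------------------------------
# independent oracles


def conv2d_oracle(img, kernel):
    """Nested-loop 2-D convolution with reflective boundary."""
    h, w = img.shape
    kh, kw = kernel.shape
    ch, cw = kh // 2, kw // 2
    out = np.zeros_like(img)

    def reflect(i, n):  # scipy 'reflect': (d c b a | a b c d | d c b a)
        while i < 0 or i >= n:
            if i < 0:
                i = -i - 1
            if i >= n:
                i = 2 * n - i - 1
        return i

    for r in range(h):
        for c in range(w):
            acc = 0.0
            for dr in range(kh):
                for dc in range(kw):
                    # true convolution: kernel flipped
                    rr = reflect(r - (dr - ch), h)
                    cc = reflect(c - (dc - cw), w)
                    acc += kernel[dr, dc] * img[rr, cc]
            out[r, c] = acc
    return out


def gaussian_blur_oracle(img, sigma):
    """Separable sampled-Gaussian blur, radius ceil(3*sigma), reflective."""
    radius = math.ceil(3 * sigma)
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-(x**2) / (2 * sigma**2))
    k /= k.sum()
    pad = np.pad(img, radius, mode="symmetric")  # half-sample reflection
    tmp = np.zeros_like(pad)
    for i, kv in enumerate(k):
        tmp += kv * np.roll(pad, radius - i, axis=0)
    out = np.zeros_like(pad)
    for i, kv in enumerate(k):
        out += kv * np.roll(tmp, radius - i, axis=1)
    return out[radius:-radius, radius:-radius]


def equalize_oracle(img, nbins):
    """Histogram equalisation straight from the cdf definition."""
    bins = np.clip((img * nbins).astype(int), 0, nbins - 1)
    hist = np.bincount(bins.ravel(), minlength=nbins)
    cdf = hist.cumsum() / bins.size
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    if 1 - cdf_min == 0:
        return img.copy()
    return (cdf[bins] - cdf_min) / (1 - cdf_min)


def clahe_oracle(img, params):
    """Per-tile mapping + bilinear blending, computed independently."""
    h, w = img.shape
    row_runs = np.array_split(np.arange(h), params.tiles_y)
    col_runs = np.array_split(np.arange(w), params.tiles_x)
    rc = [float(r.mean()) for r in row_runs]
    cc = [float(c.mean()) for c in col_runs]
    nb = params.nbins
    bins = np.clip((img * nb).astype(int), 0, nb - 1)

    def tile_map(i, j):
        tb = bins[np.ix_(row_runs[i], col_runs[j])]
        hist = np.bincount(tb.ravel(), minlength=nb).astype(float)
        if np.count_nonzero(hist) <= 1:
            return None
        if params.clip_limit is not None:
            limit = params.clip_limit * hist.sum() / nb
            excess = np.maximum(hist - limit, 0).sum()
            hist = np.minimum(hist, limit) + excess / nb
        cdf = hist.cumsum() / hist.sum()
        cdf_min = cdf[np.nonzero(hist)[0][0]]
        return np.clip((cdf - cdf_min) / (1 - cdf_min), 0, 1)

    luts = [[tile_map(i, j) for j in range(params.tiles_x)] for i in range(params.tiles_y)]

    def axis_weight(pos, centers, i):
        n = len(centers)
        if n == 1:
            return 1.0
        if i > 0 and centers[i - 1] <= pos < centers[i]:
            return (pos - centers[i - 1]) / (centers[i] - centers[i - 1])
        if i < n - 1 and centers[i] <= pos < centers[i + 1]:
            return 1 - (pos - centers[i]) / (centers[i + 1] - centers[i])
        if i == 0 and pos < centers[0]:
            return 1.0
        if i == n - 1 and pos >= centers[-1]:
            return 1.0
        return 1.0 if pos == centers[i] else 0.0

    out = np.zeros_like(img)
    for r in range(h):
        for c in range(w):
            acc = 0.0
            for i in range(params.tiles_y):
                wr = axis_weight(r, rc, i)
                if wr == 0:
                    continue
                for j in range(params.tiles_x):
                    wc = axis_weight(c, cc, j)
                    if wc == 0:
                        continue
                    lut = luts[i][j]
                    val = img[r, c] if lut is None else lut[bins[r, c]]
                    acc += wr * wc * val
            out[r, c] = acc
    return np.clip(out, 0, 1)


def lime_dense_oracle(t_hat, params):
    """Dense direct solve of the illumination refinement system."""
    h, w = t_hat.shape
    n = h * w
    dh = np.zeros((n, n))
    dv = np.zeros((n, n))
    for r in range(h):
        for c in range(w):
            i = r * w + c
            if c < w - 1:
                dh[i, i], dh[i, i + 1] = -1, 1
            if r < h - 1:
                dv[i, i], dv[i, i + w] = -1, 1
    flat = t_hat.ravel()
    a = np.eye(n)
    for d in (dh, dv):
        grad = d @ flat
        if params.weight_strategy == "inverse_gradient":
            wgt = 1.0 / (np.abs(grad) + params.epsilon)
        else:
            wgt = np.ones(n)
        a += params.alpha * d.T @ np.diag(wgt) @ d
    return np.linalg.solve(a, flat).reshape(h, w)


# ---------------------------------------------------------------------------
# sharpen


class TestSharpen:
    def test_constant_preserved(self):
        img = np.full((8, 8), 0.5)
        assert np.array_equal(sharpen(img), img)

    def test_hand_convolution_of_single_bright_pixel(self):
        img = np.zeros((9, 9))
        img[4, 4] = 0.1
        out = sharpen(img)
        assert out[4, 4] == pytest.approx(0.5)
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            assert out[4 + dr, 4 + dc] == 0.0  # clipped from -0.1
        assert out.sum() == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_nested_loop_oracle(self, seed):
        img = np.random.default_rng(seed).uniform(size=(16, 16))
        kernel = DEFAULT_SHARPEN_KERNEL
        expected = np.clip(conv2d_oracle(img, kernel), 0, 1)
        assert np.abs(sharpen(img, kernel) - expected).max() < 1e-12

    def test_asymmetric_kernel_uses_true_convolution(self):
        rng = np.random.default_rng(7)
        img = rng.uniform(size=(12, 12))
        kernel = np.array([[0.5, -0.25, 0], [0.25, 0.75, -0.5], [0, 0.25, 0.0]])
        expected = np.clip(conv2d_oracle(img, kernel), 0, 1)
        assert np.abs(sharpen(img, kernel) - expected).max() < 1e-12

    def test_non_unit_sum_kernel_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            sharpen(np.zeros((8, 8)), np.ones((3, 3)))


# ---------------------------------------------------------------------------
# histogram equalisation


class TestHistEqualize:
    def test_constant_returned_unchanged(self):
        img = np.full((8, 8), 0.42)
        assert np.array_equal(hist_equalize(img), img)

    def test_binary_image_maps_to_extremes(self):
        img = np.zeros((8, 8))
        img[:4] = 1.0
        out = hist_equalize(img, nbins=256)
        assert np.array_equal(out[:4], np.ones((4, 8)))
        assert np.array_equal(out[4:], np.zeros((4, 8)))

    def test_four_level_equal_counts(self):
        levels = np.array([0, 1 / 3, 2 / 3, 1.0])
        img = np.repeat(levels, 16).reshape(8, 8)
        out = hist_equalize(img, nbins=256)
        for lv in levels:
            assert np.allclose(out[np.isclose(img, lv)], lv, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_cdf_oracle(self, seed):
        img = np.random.default_rng(seed).uniform(size=(16, 16))
        assert np.abs(hist_equalize(img, 64) - equalize_oracle(img, 64)).max() < 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_intensity(self, seed):
        img = np.random.default_rng(seed).uniform(size=(16, 16))
        out = hist_equalize(img)
        order = np.argsort(img.ravel())
        assert np.all(np.diff(out.ravel()[order]) >= 0)

    @pytest.mark.parametrize("nbins", [64, 256])
    def test_idempotent_up_to_binning(self, nbins, random_image):
        once = hist_equalize(random_image, nbins)
        twice = hist_equalize(once, nbins)
        assert np.abs(twice - once).max() <= 2 / nbins


# ---------------------------------------------------------------------------
# CLAHE


class TestClahe:
    def test_single_unclipped_tile_equals_global_equalisation(self, random_image):
        p = ClaheParams(tiles_y=1, tiles_x=1, clip_limit=None, nbins=256)
        assert np.abs(clahe(random_image, p) - hist_equalize(random_image)).max() <= 1 / 256

    def test_constant_image_unchanged(self):
        img = np.full((16, 16), 0.3)
        assert np.array_equal(clahe(img, ClaheParams()), img)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_per_tile_oracle(self, seed):
        img = np.random.default_rng(seed).uniform(size=(16, 16))
        p = ClaheParams(tiles_y=2, tiles_x=2, clip_limit=2.0, nbins=64)
        assert np.abs(clahe(img, p) - clahe_oracle(img, p)).max() < 1e-10

    def test_unclipped_tiles_match_oracle_too(self):
        img = np.random.default_rng(99).uniform(size=(16, 16))
        p = ClaheParams(tiles_y=2, tiles_x=2, clip_limit=None, nbins=64)
        assert np.abs(clahe(img, p) - clahe_oracle(img, p)).max() < 1e-10

    def test_oversized_tile_grid_rejected(self):
        with pytest.raises(ValueError):
            clahe(np.zeros((8, 8)), ClaheParams(tiles_y=9, tiles_x=1))


# ---------------------------------------------------------------------------
# unsharp masking


class TestUnsharpMask:
    def test_zero_amount_is_identity(self, random_image):
        assert np.array_equal(unsharp_mask(random_image, sigma=1.0, amount=0.0), random_image)

    def test_constant_unchanged(self):
        img = np.full((16, 16), 0.6)
        assert np.allclose(unsharp_mask(img, 1.5, 2.0), img, atol=1e-12)

    def test_step_edge_matches_separable_oracle(self):
        img = np.zeros((16, 16))
        img[:, 8:] = 0.8
        expected = np.clip(img + 1.0 * (img - gaussian_blur_oracle(img, 1.0)), 0, 1)
        out = unsharp_mask(img, sigma=1.0, amount=1.0)
        assert np.abs(out - expected).max() < 1e-10
        # overshoot on the bright side of the edge, undershoot on the dark
        assert out[4, 8] > 0.8 and out[4, 7] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_random_images_match_oracle(self, seed):
        img = np.random.default_rng(seed).uniform(size=(16, 16))
        expected = np.clip(img + 0.7 * (img - gaussian_blur_oracle(img, 2.0)), 0, 1)
        assert np.abs(unsharp_mask(img, 2.0, 0.7) - expected).max() < 1e-10


# ---------------------------------------------------------------------------
# histogram compression


class TestCompressHistogram:
    def test_full_range_is_min_max_stretch(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0.2, 0.8, size=(16, 16))
        out = compress_histogram(img, 0, 100)
        expected = (img - img.min()) / (img.max() - img.min())
        assert np.allclose(out, expected, atol=1e-12)

    def test_constant_unchanged(self):
        img = np.full((8, 8), 0.4)
        assert np.array_equal(compress_histogram(img), img)

    def test_ramp_against_sort_based_percentile_oracle(self):
        img = (np.arange(100) / 100.0).reshape(10, 10)
        lo = np.percentile(img, 10)
        hi = np.percentile(img, 90)
        out = compress_histogram(img, 10, 90)
        expected = np.clip((img - lo) / (hi - lo), 0, 1)
        assert np.allclose(out, expected, atol=1e-12)
        assert np.all(out[img <= lo] == 0.0)
        assert np.all(out[img >= hi] == 1.0)

    def test_bad_percentiles_rejected(self):
        with pytest.raises(ValueError):
            compress_histogram(np.zeros((8, 8)), 60, 90)


# ---------------------------------------------------------------------------
# LIME


class TestLime:
    def test_alpha_zero_closed_form(self, random_image):
        p = LimeParams(alpha=0.0, gamma=0.8, epsilon=1e-3)
        t_hat = np.maximum(random_image, p.epsilon)
        expected = np.clip(random_image / np.clip(t_hat, p.epsilon, 1) ** p.gamma, 0, 1)
        assert np.allclose(lime_enhance(random_image, p), expected, atol=1e-12)

    def test_constant_image_gamma_one_maps_to_one(self):
        img = np.full((12, 12), 0.6)
        out = lime_enhance(img, LimeParams(gamma=1.0))
        assert np.allclose(out, 1.0, atol=1e-9)

    @pytest.mark.parametrize("strategy", ["inverse_gradient", "uniform"])
    def test_refinement_matches_dense_solve(self, strategy):
        rng = np.random.default_rng(3)
        img = rng.uniform(size=(12, 12))
        p = LimeParams(alpha=0.15, weight_strategy=strategy)
        t_hat = np.maximum(img, p.epsilon)
        dense = lime_dense_oracle(t_hat, p)
        sparse = refine_illumination(t_hat, p)
        assert np.abs(dense - sparse).max() < 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_never_darkens_for_gamma_below_one(self, seed):
        img = np.random.default_rng(seed).uniform(size=(12, 12))
        out = lime_enhance(img, LimeParams(gamma=0.8))
        assert np.all(out >= img - 1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            LimeParams(alpha=-1)
        with pytest.raises(ValueError):
            LimeParams(gamma=0)
        with pytest.raises(ValueError):
            LimeParams(epsilon=0.5)


# ---------------------------------------------------------------------------
# inversion and shared properties


class TestInvert:
    def test_involution(self, random_image):
        assert np.array_equal(invert(invert(random_image)), random_image)

    def test_extremes_and_midpoints(self):
        img = np.full((8, 8), 0.3)
        assert np.allclose(invert(img), 0.7)
        assert np.array_equal(invert(np.zeros((8, 8))), np.ones((8, 8)))


ALL_OPS = [
    lambda x: sharpen(x),
    lambda x: hist_equalize(x),
    lambda x: clahe(x, ClaheParams(tiles_y=4, tiles_x=4)),
    lambda x: unsharp_mask(x, 1.5, 1.0),
    lambda x: compress_histogram(x),
    lambda x: lime_enhance(x, LimeParams()),
    invert,
]


@pytest.mark.parametrize("op_idx", range(len(ALL_OPS)))
def test_all_operators_preserve_unit_range_and_determinism(op_idx):
    op = ALL_OPS[op_idx]
    for img in random_images(3, shape=(16, 16), seed=op_idx):
        out1 = op(img)
        out2 = op(img)
        assert out1.min() >= 0.0 and out1.max() <= 1.0
        assert np.array_equal(out1, out2), "operator must be bit-deterministic"
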