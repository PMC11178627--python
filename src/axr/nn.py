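"""A small convolutional network in pure numpy.

This is the desk-scale classifier backbone used by the cross-validation
harness: a stack of 3x3 convolution + ReLU + 2x2 max-pool blocks and a
flattened linear softmax head, trained with Adam on multiclass
cross-entropy.  Class probabilities come from the softmax and the
predicted label is the argmax.  The head sees the flattened feature map
rather than a pooled average because the class-discriminating features
of radiographs are small and localised.

Internally activations are kept channels-last (N, H, W, C) and
convolutions are im2col matrix multiplications, which keeps the whole
training loop inside BLAS and fast enough on one CPU for the
few-thousand-step runs the harness performs.  Everything is float32 and
fully seeded.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SmallCNN"]


def _im2col(x: np.ndarray, k: int = 3) -> np.ndarray:
    """(N, H, W, C) -> (N, H*W, k*k*C) patches with zero padding k//2."""
    n, h, w, c = x.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # (N, H, W, C, k, k) -> rows ordered (k, k, C) to match the weight layout
    cols = windows.transpose(0, 1, 2, 4, 5, 3).reshape(n, h * w, k * k * c)
    return np.ascontiguousarray(cols)


def _col2im(cols: np.ndarray, shape: tuple[int, ...], k: int = 3) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back to (N, H, W, C)."""
    n, h, w, c = shape
    pad = k // 2
    out = np.zeros((n, h + 2 * pad, w + 2 * pad, c), dtype=cols.dtype)
    patches = cols.reshape(n, h, w, k, k, c)
    for di in range(k):
        for dj in range(k):
            out[:, di : di + h, dj : dj + w, :] += patches[:, :, :, di, dj, :]
    return out[:, pad : pad + h, pad : pad + w, :]


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SmallCNN:
    """Conv-ReLU-pool blocks + flatten + linear softmax head.

    Parameters
    ----------
    in_channels : input planes (3 for pipeline output)
    n_classes : number of output classes
    channels : filters per conv block; each block halves the spatial
        extent, so ``input_size`` must be divisible by ``2**len(channels)``
    input_size : spatial side length of the (square) input
    lr : Adam learning rate
    seed : weight-initialisation seed
    """

    def __init__(
        self,
        in_channels: int = 3,
        n_classes: int = 3,
        channels: tuple[int, ...] = (8, 16, 32, 32),
        input_size: int = 48,
        lr: float = 1e-3,
        seed: int = 0,
    ) -> None:
        if input_size % (2 ** len(channels)) != 0:
            raise ValueError(
                f"input_size {input_size} not divisible by 2**{len(channels)}"
            )
        self.channels = tuple(channels)
        self.input_size = input_size
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        prev = in_channels
        for ch in channels:
            fan_in = prev * 9
            w = rng.normal(0, np.sqrt(2.0 / fan_in), size=(9 * prev, ch)).astype(
                np.float32
            )
            self.weights.append(w)
            self.biases.append(np.zeros(ch, dtype=np.float32))
            prev = ch
        side = input_size // (2 ** len(channels))
        feat_dim = prev * side * side
        self.head_w = rng.normal(
            0, np.sqrt(1.0 / feat_dim), size=(feat_dim, n_classes)
        ).astype(np.float32)
        self.head_b = np.zeros(n_classes, dtype=np.float32)
        params = self.weights + self.biases + [self.head_w, self.head_b]
        self.opt = _Adam(params, lr)

    # ----- forward ---------------------------------------------------------

    def _forward(self, x: np.ndarray, keep_cache: bool = True) -> tuple[np.ndarray, list]:
        if x.ndim != 4:
            raise ValueError(f"expected (N, C, H, W) input, got shape {x.shape}")
        out = np.ascontiguousarray(
            x.transpose(0, 2, 3, 1), dtype=np.float32
        )  # to channels-last
        cache = []
        for w, b in zip(self.weights, self.biases):
            n, h, wd, _ = out.shape
            cols = _im2col(out)
            pre = (cols @ w + b).reshape(n, h, wd, -1)
            relu_mask = pre > 0
            act = pre * relu_mask
            c = act.shape[-1]
            # 2x2 max pool via a (n, h/2, w/2, 4, c) window view
            quads = np.ascontiguousarray(
                act.reshape(n, h // 2, 2, wd // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
            ).reshape(n, h // 2, wd // 2, 4, c)
            argmax = quads.argmax(axis=3)
            pooled = np.take_along_axis(quads, argmax[:, :, :, None, :], axis=3)[
                :, :, :, 0, :
            ]
            if keep_cache:
                cache.append((out.shape, cols, relu_mask, argmax))
            out = pooled
        feat = out.reshape(out.shape[0], -1)
        logits = feat @ self.head_w + self.head_b
        if keep_cache:
            cache.append((out.shape, feat))
        return logits, cache

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        logits, _ = self._forward(x, keep_cache=False)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    # ----- backward --------------------------------------------------------

    def train_batch(self, x: np.ndarray, y: np.ndarray) -> float:
        """One Adam step on a batch; returns the mean cross-entropy loss."""
        logits, cache = self._forward(x)
        n = x.shape[0]
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs = e / e.sum(axis=1, keepdims=True)
        loss = float(-np.log(probs[np.arange(n), y] + 1e-12).mean())
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite training loss")

        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n

        pooled_shape, feat = cache[-1]
        d_head_w = feat.T @ dlogits
        d_head_b = dlogits.sum(axis=0)
        dpool = (dlogits @ self.head_w.T).reshape(pooled_shape)

        grads_w: list[np.ndarray] = []
        grads_b: list[np.ndarray] = []
        n_blocks = len(self.weights)
        for layer, ((in_shape, cols, relu_mask, argmax), w) in enumerate(
            zip(reversed(cache[:-1]), reversed(self.weights))
        ):
            # unpool: route the gradient to the argmax position of each quad
            nb, h2, w2, co = dpool.shape
            dquads = np.zeros((nb, h2, w2, 4, co), dtype=np.float32)
            np.put_along_axis(dquads, argmax[:, :, :, None, :], dpool[:, :, :, None, :], axis=3)
            dact = (
                dquads.reshape(nb, h2, w2, 2, 2, co)
                .transpose(0, 1, 3, 2, 4, 5)
                .reshape(relu_mask.shape)
            )
            dpre = dact * relu_mask
            h, wd = dpre.shape[1], dpre.shape[2]
            dpre2 = dpre.reshape(nb * h * wd, co)
            cols2 = cols.reshape(nb * h * wd, -1)
            grads_w.append(cols2.T @ dpre2)
            grads_b.append(dpre2.sum(axis=0))
            if layer < n_blocks - 1:  # no input gradient needed at the first conv
                dcols = dpre.reshape(nb, h * wd, co) @ w.T
                dpool = _col2im(dcols, in_shape)

        grads = (
            list(reversed(grads_w))
            + list(reversed(grads_b))
            + [d_head_w.astype(np.float32), d_head_b.astype(np.float32)]
        )
        self.opt.step(grads)
        return loss
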