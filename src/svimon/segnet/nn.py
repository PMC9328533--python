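"""Minimal NumPy neural-network layers with backpropagation.

All activations are float32 tensors in NCHW layout. Convolutions are
stride-1 with 'same' zero padding, computed by im2col + matrix multiply; the
input gradient reuses the same machinery as a convolution with the spatially
flipped, channel-transposed kernel.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "Upsample2",
    "Concat",
    "Dropout",
    "softmax_channel",
    "softmax_cross_entropy",
]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) patch matrix under same padding."""
    n, c, h, w = x.shape
    if k == 1:
        return x.transpose(0, 2, 3, 1).reshape(n * h * w, c)
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    # windows: (N, C, H, W, k, k)
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * h * w, c * k * k
    )


class Conv2D:
    """Stride-1 'same' convolution with bias."""

    def __init__(self, cin: int, cout: int, k: int = 3, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * k * k))  # He init for ReLU nets
        self.w = rng.normal(0.0, scale, size=(cout, cin, k, k)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.k = k
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x, self.k)
        w2 = self.w.reshape(self.w.shape[0], -1).T  # (cin*k*k, cout)
        y = cols @ w2 + self.b
        if train:
            self._cols, self._shape = cols, x.shape
        return y.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, cout, h, w = dy.shape
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(n * h * w, cout)
        self.dw += (self._cols.T @ dyf).T.reshape(self.w.shape)
        self.db += dyf.sum(axis=0)
        # dx = dy convolved with the flipped kernel, channels transposed
        wb = self.w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (cin, cout, k, k)
        cols_dy = _im2col(dy, self.k)
        dx = cols_dy @ wb.reshape(wb.shape[0], -1).T
        cin = self._shape[1]
        self._cols = None
        return dx.reshape(n, h, w, cin).transpose(0, 3, 1, 2)


class ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2; ties route the gradient to the first max."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        x4 = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x4 = np.ascontiguousarray(x4).reshape(n, c, h // 2, w // 2, 4)
        if train:
            self._idx = x4.argmax(axis=-1)
            self._shape = x.shape
        return x4.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, hh, ww = dy.shape
        d4 = np.zeros((n, c, hh, ww, 4), dtype=dy.dtype)
        np.put_along_axis(d4, self._idx[..., None], dy[..., None], axis=-1)
        d4 = d4.reshape(n, c, hh, ww, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(d4).reshape(self._shape)


class Upsample2:
    """Nearest-neighbour 2x upsampling."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Concat:
    """Channel-axis concatenation of (skip, x)."""

    def params(self):
        return []

    def forward(self, skip: np.ndarray, x: np.ndarray) -> np.ndarray:
        self._split = skip.shape[1]
        return np.concatenate([skip, x], axis=1)

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return dy[:, : self._split], dy[:, self._split :]


class Dropout:
    """Inverted dropout; active only when ``train`` is set."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


def softmax_channel(logits: np.ndarray) -> np.ndarray:
    """Channel-axis softmax of an (N, C, H, W) tensor."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Categorical cross-entropy over pixels.

    ``targets`` is an (N, H, W) integer class raster. Returns
    ``(loss, dlogits, probs)`` with the gradient averaged over all pixels.
    """
    probs = softmax_channel(logits)
    n, c, h, w = logits.shape
    idx_n, idx_h, idx_w = np.ogrid[:n, :h, :w]
    p_true = probs[idx_n, targets, idx_h, idx_w]
    loss = float(-np.log(np.maximum(p_true, 1e-12)).mean())
    onehot = np.zeros_like(probs)
    onehot[idx_n, targets, idx_h, idx_w] = 1.0
    dlogits = (probs - onehot) / (n * h * w)
    return loss, dlogits.astype(np.float32), probs
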