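"""Minimal numpy layers with hand-written backprop.

Only what the encoder-decoder segmentation network needs: same-size
convolution, ReLU, batch norm, 2x2 max pooling, 2x2 stride-2 transposed
convolution and dropout.  Tensors are NCHW float64; each layer caches
what its backward pass needs on forward.

Convolutions use ``sliding_window_view`` + ``tensordot`` so the heavy
lifting stays in BLAS; this trains the small networks used here on a
single CPU in minutes, which is all the package requires.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "ConvTranspose2x2",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2x2",
    "Dropout",
]


class Layer:
    """Base: forward/backward plus flat parameter access for the optimizer."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)


class Conv2d(Layer):
    """Stride-1 zero-padded ("same") convolution, odd square kernel."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for size parity")
        self.k = kernel
        # He initialization: small random values scaled by fan-in
        fan_in = c_in * kernel * kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel, kernel))
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # windows: (N, C, H, W, k, k)
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        if train:
            self._win = win
        out = np.tensordot(win, self.W, axes=([1, 4, 5], [1, 2, 3]))
        # out: (N, H, W, O) -> NCHW
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2)) + self.b[None, :, None, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        p = self.k // 2
        g = gout.transpose(0, 2, 3, 1)  # (N, H, W, O)
        self.grads[0][...] = np.tensordot(g, self._win, axes=([0, 1, 2], [0, 2, 3]))  # (O,C,k,k)
        self.grads[1][...] = gout.sum(axis=(0, 2, 3))
        # gradient wrt input: full correlation of gout with flipped kernels
        gp = np.pad(gout, ((0, 0), (0, 0), (p, p), (p, p)))
        gwin = sliding_window_view(gp, (self.k, self.k), axis=(2, 3))  # (N, O, H, W, k, k)
        Wf = self.W[:, :, ::-1, ::-1]
        gx = np.tensordot(gwin, Wf, axes=([1, 4, 5], [0, 2, 3]))  # (N, H, W, C)
        del self._win
        return np.ascontiguousarray(gx.transpose(0, 3, 1, 2))


class ConvTranspose2x2(Layer):
    """2x2 kernel, stride-2 transposed convolution (exact 2x upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        fan_in = c_in * 4
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_in, c_out, 2, 2))
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        n, c, h, w = x.shape
        # out[n, o, 2i+a, 2j+b] = sum_c x[n,c,i,j] W[c,o,a,b]
        t = np.tensordot(x, self.W, axes=([1], [0]))  # (N, H, W, O, 2, 2)
        t = t.transpose(0, 3, 1, 4, 2, 5)  # (N, O, H, 2, W, 2)
        out = t.reshape(n, self.W.shape[1], 2 * h, 2 * w)
        return out + self.b[None, :, None, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, o, H, W2 = gout.shape
        h, w = H // 2, W2 // 2
        g = gout.reshape(n, o, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)  # (N,h,w,O,2,2)
        self.grads[0][...] = np.tensordot(self._x, g, axes=([0, 2, 3], [0, 1, 2]))
        self.grads[1][...] = gout.sum(axis=(0, 2, 3))
        gx = np.tensordot(g, self.W, axes=([3, 4, 5], [1, 2, 3]))  # (N, h, w, C)
        del self._x
        return np.ascontiguousarray(gx.transpose(0, 3, 1, 2))


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics.

    Batch statistics during training; running (frozen) statistics at
    inference.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
            self._cache = (xhat, inv, x.shape[0] * x.shape[2] * x.shape[3])
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean[None, :, None, None]) * inv[None, :, None, None]
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, inv, m = self._cache
        self.grads[0][...] = (gout * xhat).sum(axis=(0, 2, 3))
        self.grads[1][...] = gout.sum(axis=(0, 2, 3))
        gxhat = gout * self.gamma[None, :, None, None]
        term1 = gxhat
        term2 = gxhat.mean(axis=(0, 2, 3), keepdims=True)
        term3 = xhat * (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        del self._cache
        return inv[None, :, None, None] * (term1 - term2 - term3)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        gx = gout * self._mask
        del self._mask
        return gx


class MaxPool2x2(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial size must be even for 2x2 pooling")
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4
        )
        idx = r.argmax(axis=-1)
        if train:
            self._idx = idx
            self._shape = x.shape
        return np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        flat = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(flat, self._idx[..., None], gout[..., None], axis=-1)
        gx = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h, w
        )
        del self._idx, self._shape
        return gx


class Dropout(Layer):
    """Inverted dropout; active only during training, seeded externally."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0:
            return x
        if self.rng is None:
            raise RuntimeError("dropout used in training without a seeded generator")
        mask = self.rng.random(x.shape) >= self.rate
        self._mask = mask / (1.0 - self.rate)
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        if not hasattr(self, "_mask"):
            return gout
        gx = gout * self._mask
        del self._mask
        return gx
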