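"""Minimal NumPy neural-network layers with manual backpropagation.

Implements exactly the pieces a 2D U-Net needs — same-padding 3x3/1x1
convolution (im2col), batch normalization, ReLU, 2x2 max pooling, 2x
nearest-neighbour upsampling — plus the Adam optimizer.  Tensors are NCHW
float32; every layer caches what its backward pass needs, so the calling
code runs forward once, then backward in reverse order.

All randomness (initialization) flows through an explicit Generator, so
builds and training runs are bit-reproducible on a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "BatchNorm2d", "ReLU", "MaxPool2", "Upsample2", "Adam", "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Conv2d:
    """Same-padding convolution, kernel k x k, stride 1, He-initialized."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        self.cin, self.cout, self.k = in_channels, out_channels, kernel
        fan_in = in_channels * kernel * kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(fan_in, out_channels)).astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._xshape = None

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        # (N, C, H, W, k, k) -> (N*H*W, C*k*k)
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * self.k * self.k)

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        cols = self._im2col(x)
        y = cols @ self.W + self.b
        if training:
            self._cols, self._xshape = cols, x.shape
        return y.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        dyf = dy.transpose(0, 2, 3, 1).reshape(-1, self.cout)
        self.dW += self._cols.T @ dyf
        self.db += dyf.sum(axis=0)
        dcols = (dyf @ self.W.T).reshape(n, h, w, c, self.k, self.k)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # (N, C, H, W, k, k)
        p = self.k // 2
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j]
        self._cols = None
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class BatchNorm2d:
    """Per-channel normalization with running statistics for inference."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    @property
    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * ivar[None, :, None, None]
        if training:
            self._cache = (xhat, ivar, x.shape)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, ivar, shape = self._cache
        m = shape[0] * shape[2] * shape[3]
        self.dgamma += (dy * xhat).sum(axis=(0, 2, 3))
        self.dbeta += dy.sum(axis=(0, 2, 3))
        g = (self.gamma * ivar)[None, :, None, None]
        sum_dy = dy.sum(axis=(0, 2, 3))[None, :, None, None]
        sum_dyx = (dy * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        dx = g / m * (m * dy - sum_dy - xhat * sum_dyx)
        self._cache = None
        return dx.astype(np.float32)


class ReLU:
    params: list = []

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2:
    """2x2 max pooling, stride 2; requires even spatial dimensions."""

    params: list = []

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if training:
            self._idx, self._shape = idx, x.shape
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._idx = None
        return dx.reshape(n, c, h, w)


class Upsample2:
    """Nearest-neighbour 2x upsampling."""

    params: list = []

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Adam:
    """Adaptive-moment optimizer over a list of (param, grad) pairs."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
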