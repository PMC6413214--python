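"""Minimal NumPy neural-network layers with hand-written backprop.

Feature maps are [H, W, C] float32, single image per step.  Convolution
is im2col + GEMM; its input gradient is computed as a convolution of the
output gradient with the spatially flipped, transposed kernel, so no
scatter-add is needed.  Max pooling stores its argmax indices, which the
paired max-unpooling layer reuses.
"""

from __future__ import annotations

import numpy as np


class Layer:
    def parameters(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """(name, value, gradient) triples; gradients are overwritten in backward."""
        return []


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero padding, with bias.

    Implemented as nine shifted channel-mixing GEMMs on the padded
    input, which avoids the memory traffic of an im2col unfold.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        std = np.sqrt(2.0 / (9 * c_in))
        self.weight = rng.normal(0.0, std, size=(c_in, 3, 3, c_out)).astype(np.float32)
        self.bias = np.zeros(c_out, dtype=np.float32)
        self.d_weight = np.zeros_like(self.weight)
        self.d_bias = np.zeros_like(self.bias)
        self._xp: np.ndarray | None = None

    @staticmethod
    def _conv(xp: np.ndarray, weight: np.ndarray, h: int, w: int,
              c_out: int) -> np.ndarray:
        """Correlate a padded [H+2, W+2, Cin] input with [Cin, 3, 3, Cout]."""
        y = np.zeros((h * w, c_out), dtype=np.float32)
        for kh in range(3):
            for kw in range(3):
                window = xp[kh:kh + h, kw:kw + w, :].reshape(h * w, -1)
                y += window @ weight[:, kh, kw, :]
        return y.reshape(h, w, c_out)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h, w, _ = x.shape
        xp = np.pad(x, ((1, 1), (1, 1), (0, 0)))
        if train:
            self._xp = xp
        return self._conv(xp, self.weight, h, w, self.c_out) + self.bias

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h, w, _ = dy.shape
        dyf = dy.reshape(h * w, self.c_out)
        for kh in range(3):
            for kw in range(3):
                window = self._xp[kh:kh + h, kw:kw + w, :].reshape(h * w, -1)
                self.d_weight[:, kh, kw, :] = window.T @ dyf
        self.d_bias[...] = dyf.sum(axis=0)
        # input gradient = conv of dy with the flipped, transposed kernel
        w_back = np.ascontiguousarray(
            self.weight[:, ::-1, ::-1, :].transpose(3, 1, 2, 0))
        dyp = np.pad(dy, ((1, 1), (1, 1), (0, 0)))
        self._xp = None
        return self._conv(dyp, w_back, h, w, self.c_in)

    def parameters(self):
        return [("weight", self.weight, self.d_weight), ("bias", self.bias, self.d_bias)]


class BatchNorm(Layer):
    """Per-channel normalization over the spatial dimensions.

    With one image per step this is instance normalization, so inference
    also uses the per-image statistics: at the bottleneck the spatial
    sample is far too small (tens of pixels) for running averages to be
    a stable surrogate, and mixing train-stat training with running-stat
    inference destabilizes as the scale parameters grow.
    """

    def __init__(self, c: int, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.d_gamma = np.zeros_like(self.gamma)
        self.d_beta = np.zeros_like(self.beta)
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mean = x.mean(axis=(0, 1))
        var = x.var(axis=(0, 1))
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._cache = (xhat, inv)
        return (self.gamma * xhat + self.beta).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        n = dy.shape[0] * dy.shape[1]
        self.d_gamma[...] = (dy * xhat).sum(axis=(0, 1))
        self.d_beta[...] = dy.sum(axis=(0, 1))
        dxhat = dy * self.gamma
        dx = inv * (dxhat - dxhat.mean(axis=(0, 1))
                    - xhat * (dxhat * xhat).sum(axis=(0, 1)) / n)
        self._cache = None
        return dx.astype(np.float32)

    def parameters(self):
        return [("gamma", self.gamma, self.d_gamma), ("beta", self.beta, self.d_beta)]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0.0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2x2(Layer):
    """2x2/stride-2 max pooling; argmax indices are kept for unpooling."""

    def __init__(self):
        self.indices: np.ndarray | None = None

    @staticmethod
    def _windows(x: np.ndarray) -> np.ndarray:
        h, w, c = x.shape
        return x.reshape(h // 2, 2, w // 2, 2, c).transpose(0, 2, 1, 3, 4).reshape(
            h // 2, w // 2, 4, c)

    @staticmethod
    def _unwindows(z: np.ndarray) -> np.ndarray:
        h2, w2, _, c = z.shape
        return z.reshape(h2, w2, 2, 2, c).transpose(0, 2, 1, 3, 4).reshape(
            2 * h2, 2 * w2, c)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.shape[0] % 2 or x.shape[1] % 2:
            raise ValueError(f"spatial dims must be even, got {x.shape}")
        win = self._windows(x)
        idx = win.argmax(axis=2)
        self.indices = idx
        return np.take_along_axis(win, idx[:, :, None, :], axis=2)[:, :, 0, :]

    def scatter(self, g: np.ndarray) -> np.ndarray:
        """Place g at the stored argmax positions (used by unpool forward
        and by this layer's own backward)."""
        z = np.zeros(g.shape[:2] + (4, g.shape[2]), dtype=g.dtype)
        np.put_along_axis(z, self.indices[:, :, None, :], g[:, :, None, :], axis=2)
        return self._unwindows(z)

    def gather(self, dy: np.ndarray) -> np.ndarray:
        win = self._windows(dy)
        return np.take_along_axis(win, self.indices[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.scatter(dy)


class MaxUnpool2x2(Layer):
    """Upsample by placing values at the paired pooling layer's indices."""

    def __init__(self, pool: MaxPool2x2):
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.pool.scatter(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.pool.gather(dy)


class ConvBlock(Layer):
    """conv(3x3) -> batch norm -> ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv = Conv3x3(c_in, c_out, rng)
        self.bn = BatchNorm(c_out)
        self.relu = ReLU()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.relu.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.bn.backward(self.relu.backward(dy)))

    def parameters(self):
        return [(f"conv.{n}", v, g) for n, v, g in self.conv.parameters()] + \
               [(f"bn.{n}", v, g) for n, v, g in self.bn.parameters()]


class Adam:
    """Adam over a flat list of (value, gradient) array pairs."""

    def __init__(self, params: list[tuple[str, np.ndarray, np.ndarray]],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(v) for _, v, _ in params]
        self.v = [np.zeros_like(v) for _, v, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        bias1 = 1.0 - self.b1 ** self.t
        bias2 = 1.0 - self.b2 ** self.t
        for (name, val, grad), m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (grad - m)
            v += (1.0 - self.b2) * (grad * grad - v)
            val -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
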