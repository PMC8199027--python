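"""Minimal NumPy convnet: layers with explicit forward/backward, SGD.

Everything operates on float32 NCHW tensors.  Convolutions are implemented
with strided im2col views and a single GEMM per layer, which is the fastest
pure-NumPy formulation for the small backbones used here.  No padding is
ever applied, so exact translation equivariance by the product of the
layer strides holds on interior cells.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "Sequential",
    "SGD",
]


def _im2col(x: np.ndarray, k: int, stride: int) -> tuple[np.ndarray, int, int]:
    """(N,C,H,W) -> (N, C*k*k, Ho*Wo) patch matrix.

    Built with k*k contiguous slice copies (one per kernel offset), which
    is far faster on one core than a single strided gather.
    """
    n, c, h, w = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    if ho < 1 or wo < 1:
        raise ValueError(f"input {h}x{w} too small for kernel {k} stride {stride}")
    cols = np.empty((n, c, k, k, ho, wo), dtype=x.dtype)
    if stride == 1:
        for i in range(k):
            for j in range(k):
                cols[:, :, i, j] = x[:, :, i : i + ho, j : j + wo]
    else:
        # split into stride x stride contiguous phase images so every kernel
        # offset becomes a unit-stride slice (one strided pass instead of k*k)
        phases = [
            [np.ascontiguousarray(x[:, :, p::stride, q::stride]) for q in range(stride)]
            for p in range(stride)
        ]
        for i in range(k):
            for j in range(k):
                ph = phases[i % stride][j % stride]
                cols[:, :, i, j] = ph[
                    :, :, i // stride : i // stride + ho, j // stride : j // stride + wo
                ]
    return cols.reshape(n, c * k * k, ho * wo), ho, wo


def _col2im(
    dcols: np.ndarray, x_shape: tuple, k: int, stride: int, ho: int, wo: int
) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patch gradients back to the image."""
    n, c, h, w = x_shape
    dx = np.zeros(x_shape, dtype=dcols.dtype)
    d = dcols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += d[
                :, :, i, j
            ]
    return dx


class Layer:
    train_mode = False

    def params(self):
        return {}

    def grads(self):
        return {}


class Conv2d(Layer):
    """Valid (padding-free) 2D convolution with bias."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1, *, rng=None):
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        self.W = (rng.standard_normal((cout, fan_in)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, ho, wo = _im2col(x, self.k, self.stride)
        out = np.matmul(self.W, cols) + self.b[:, None]
        self._cache = (cols, x.shape, ho, wo)
        n = x.shape[0]
        return out.reshape(n, self.cout, ho, wo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape, ho, wo = self._cache
        n = dout.shape[0]
        dflat = dout.reshape(n, self.cout, ho * wo)
        dcols = np.empty_like(cols)
        for b in range(n):  # looped 2D GEMMs: BLAS handles the .T views in place
            self.dW += dflat[b] @ cols[b].T
            dcols[b] = self.W.T @ dflat[b]
        self.db += dflat.sum(axis=(0, 2))
        return _col2im(dcols, x_shape, self.k, self.stride, ho, wo)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.train_mode:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return (
            self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]
        ).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        m = shape[0] * shape[2] * shape[3]
        self.dgamma += (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
        ) * inv[None, :, None, None]
        return dx.astype(np.float32)

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2d(Layer):
    def __init__(self, k: int = 3, stride: int = 2):
        self.k, self.stride = k, stride

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, st = self.k, self.stride
        ho = (h - k) // st + 1
        wo = (w - k) // st + 1
        if st > 1:
            phases = [
                [np.ascontiguousarray(x[:, :, p::st, q::st]) for q in range(st)]
                for p in range(st)
            ]
            out = None
            for i in range(k):
                for j in range(k):
                    ph = phases[i % st][j % st]
                    sub = ph[:, :, i // st : i // st + ho, j // st : j // st + wo]
                    out = sub.copy() if out is None else np.maximum(out, sub, out=out)
        else:
            out = x[:, :, :ho, :wo].copy()
            for i in range(k):
                for j in range(k):
                    np.maximum(out, x[:, :, i : i + ho, j : j + wo], out=out)
        self._cache = (x, out, ho, wo)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, out, ho, wo = self._cache
        k, st = self.k, self.stride
        dx = np.zeros_like(x)
        for i in range(k):
            for j in range(k):
                sub = x[:, :, i : i + ho * st : st, j : j + wo * st : st]
                mask = sub == out
                dx[:, :, i : i + ho * st : st, j : j + wo * st : st] += dout * mask
        return dx


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def set_train(self, flag: bool) -> None:
        for lay in self.layers:
            lay.train_mode = flag

    def forward(self, x: np.ndarray) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for lay in reversed(self.layers):
            dout = lay.backward(dout)
        return dout

    def zero_grad(self) -> None:
        for lay in self.layers:
            for g in lay.grads().values():
                g[...] = 0.0

    def named_params(self):
        for i, lay in enumerate(self.layers):
            for name, p in lay.params().items():
                yield f"layer{i}.{name}", p, lay.grads()[name]


class SGD:
    """SGD with momentum and decoupled-from-nothing classic weight decay."""

    def __init__(self, momentum: float = 0.9, weight_decay: float = 0.0):
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel: dict[str, np.ndarray] = {}

    def step(self, named_params, lr: float) -> None:
        for name, p, g in named_params:
            v = self._vel.setdefault(name, np.zeros_like(p))
            upd = g + self.weight_decay * p
            v *= self.momentum
            v -= lr * upd
            p += v
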