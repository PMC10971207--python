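"""Minimal NumPy layers with hand-written backpropagation.

Only what the fully convolutional segmentation networks need: Conv2d (im2col
over a BLAS matmul), BatchNorm2d, ReLU, 2-D max pooling and nearest-neighbor
upsampling.  Tensors are float32 arrays of shape (B, C, H, W).  Each layer
caches what its backward pass needs during forward; `backward(grad_out)`
returns grad wrt the input and accumulates parameter gradients.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Param", "Layer", "Conv2d", "BatchNorm2d", "ReLU", "MaxPool2d", "NearestUpsample"]


class Param:
    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    training: bool = True

    def parameters(self) -> list[Param]:
        return []

    def train(self, mode: bool = True) -> None:
        self.training = mode

    def state(self) -> dict[str, np.ndarray]:
        return {}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        pass


class Conv2d(Layer):
    """k x k convolution, stride s, symmetric zero padding (default 'same')."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        pad: int | None = None,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, kernel, stride
        self.pad = pad if pad is not None else kernel // 2
        fan_in = in_ch * kernel * kernel
        w = rng.standard_normal((out_ch, fan_in)) * np.sqrt(2.0 / fan_in)  # He init
        self.weight = Param(w)
        self.bias = Param(np.zeros(out_ch)) if bias else None

    def parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def state(self):
        s = {"weight": self.weight.data}
        if self.bias is not None:
            s["bias"] = self.bias.data
        return s

    def load_state(self, state):
        self.weight.data[...] = state["weight"]
        if self.bias is not None:
            self.bias.data[...] = state["bias"]

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        b, c, h, w = x.shape
        p, k, s = self.pad, self.k, self.stride
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        hp, wp = x.shape[2], x.shape[3]
        ho = (hp - k) // s + 1
        wo = (wp - k) // s + 1
        v = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]  # B,C,Ho,Wo,k,k
        cols = np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(
            b * ho * wo, c * k * k
        )
        return cols, (b, c, h, w, hp, wp, ho, wo)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {x.shape[1]}")
        cols, geom = self._im2col(x)
        y = cols @ self.weight.data.T
        if self.bias is not None:
            y += self.bias.data
        self._cache = (cols, geom)
        return np.ascontiguousarray(
            y.reshape(geom[0], geom[6], geom[7], self.out_ch).transpose(0, 3, 1, 2)
        )

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols, (b, c, h, w, hp, wp, ho, wo) = self._cache
        k, s, p = self.k, self.stride, self.pad
        g2 = np.ascontiguousarray(gy.transpose(0, 2, 3, 1)).reshape(-1, self.out_ch)
        self.weight.grad += g2.T @ cols
        if self.bias is not None:
            self.bias.grad += g2.sum(axis=0)
        gcols = (g2 @ self.weight.data).reshape(b, ho, wo, c, k, k)
        gxp = np.zeros((b, c, hp, wp), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                gxp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s] += gcols[
                    :, :, :, :, ki, kj
                ].transpose(0, 3, 1, 2)
        self._cache = None
        if p:
            return gxp[:, :, p:hp - p, p:wp - p]
        return gxp


class BatchNorm2d(Layer):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        self.ch, self.eps, self.momentum = ch, eps, momentum
        self.gamma = Param(np.ones(ch))
        self.beta = Param(np.zeros(ch))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)

    def parameters(self):
        return [self.gamma, self.beta]

    def state(self):
        return {
            "gamma": self.gamma.data,
            "beta": self.beta.data,
            "running_mean": self.running_mean,
            "running_var": self.running_var,
        }

    def load_state(self, state):
        self.gamma.data[...] = state["gamma"]
        self.beta.data[...] = state["beta"]
        self.running_mean[...] = state["running_mean"]
        self.running_var[...] = state["running_var"]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        n = shape[0] * shape[2] * shape[3]
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None]
        if self.training:
            sum_gy = gy.sum(axis=(0, 2, 3), keepdims=True).transpose(1, 0, 2, 3).reshape(1, -1, 1, 1)
            sum_gy_xhat = (gy * xhat).sum(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
            gx = (g * inv[None, :, None, None] / n) * (
                n * gy - sum_gy - xhat * sum_gy_xhat
            )
        else:
            gx = g * inv[None, :, None, None] * gy
        self._cache = None
        return gx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = np.where(self._mask, gy, 0.0).astype(np.float32)
        self._mask = None
        return g


class MaxPool2d(Layer):
    """k x k max pooling with stride s and zero padding (used by the deep stem)."""

    def __init__(self, kernel: int = 3, stride: int = 2, pad: int = 1):
        self.k, self.stride, self.pad = kernel, stride, pad

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        v = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        ho, wo = v.shape[2], v.shape[3]
        flat = v.reshape(b, c, ho, wo, k * k)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        self._cache = (arg, (b, c, h, w, xp.shape[2], xp.shape[3], ho, wo))
        return np.ascontiguousarray(out.astype(np.float32))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        arg, (b, c, h, w, hp, wp, ho, wo) = self._cache
        k, s, p = self.k, self.stride, self.pad
        gxp = np.zeros((b, c, hp, wp), dtype=np.float32)
        ki, kj = np.divmod(arg, k)
        rows = (np.arange(ho)[None, None, :, None] * s) + ki
        cols = (np.arange(wo)[None, None, None, :] * s) + kj
        bb = np.arange(b)[:, None, None, None]
        cc = np.arange(c)[None, :, None, None]
        np.add.at(gxp, (bb, cc, rows, cols), gy)
        self._cache = None
        if p:
            return gxp[:, :, p:hp - p, p:wp - p]
        return gxp


class NearestUpsample(Layer):
    def __init__(self, factor: int):
        self.factor = factor

    def forward(self, x: np.ndarray) -> np.ndarray:
        f = self.factor
        return np.repeat(np.repeat(x, f, axis=2), f, axis=3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        f = self.factor
        b, c, h, w = gy.shape
        return gy.reshape(b, c, h // f, f, w // f, f).sum(axis=(3, 5)).astype(np.float32)
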