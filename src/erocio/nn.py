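"""Minimal CNN building blocks in numpy (forward + backward + Adam).

The multi-task networks used here are small (a few 5x5 conv layers, one
max-pool, one dense head per branch), so a compact im2col implementation is
sufficient and keeps the whole training loop dependency-free and exactly
seedable.  All arrays are float64; gradients are verified against finite
differences in the test suite.

Layout convention: feature maps are (batch, channels, height, width).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: parameterized layers expose params/grads dicts."""

    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """5x5 (or kxk) convolution with 'same' zero padding, stride 1."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 5, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        # He-style init scaled for the leaky-rectifier that follows
        fan_in = in_ch * kernel * kernel
        self.kernel = kernel
        self.pad = kernel // 2
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel, kernel))
        self.params["b"] = np.zeros(out_ch)

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.kernel, self.pad
        B, C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (B, C, H, W, k, k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * W, C * k * k)
        Wm = self.params["W"].reshape(self.params["W"].shape[0], -1)
        out = cols @ Wm.T + self.params["b"]
        self._cache = (cols, x.shape)
        return out.reshape(B, H, W, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        B, C, H, W = xshape
        k, p = self.kernel, self.pad
        dmat = dout.transpose(0, 2, 3, 1).reshape(B * H * W, -1)
        Wm = self.params["W"].reshape(self.params["W"].shape[0], -1)
        self.grads["W"] = (dmat.T @ cols).reshape(self.params["W"].shape)
        self.grads["b"] = dmat.sum(axis=0)
        dcols = (dmat @ Wm).reshape(B, H, W, C, k, k)
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + H, j : j + W] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + H, p : p + W]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, self.slope * dout)


class MaxPool2D(Layer):
    """2x2 max-pooling with stride 2 (input spatial dims must be even)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        xr = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(B, C, H // 2, W // 2, 4)
        self._argmax = xr.argmax(axis=-1)
        self._xshape = x.shape
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, H, W = self._xshape
        dxr = np.zeros((B, C, H // 2, W // 2, 4))
        np.put_along_axis(dxr, self._argmax[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(B, C, H, W)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["W"] = rng.normal(0.0, np.sqrt(1.0 / n_in), size=(n_in, n_out))
        self.params["b"] = np.zeros(n_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameterized(self) -> list[Layer]:
        return [l for l in self.layers if l.params]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Adam:
    """Adam optimizer over a list of parameterized layers."""

    def __init__(self, layers: list[Layer], lr: float = 1e-5, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.layers = layers
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                grad = layer.grads[k]
                self.m[i][k] = self.b1 * self.m[i][k] + (1 - self.b1) * grad
                self.v[i][k] = self.b2 * self.v[i][k] + (1 - self.b2) * grad**2
                m_hat = self.m[i][k] / b1t
                v_hat = self.v[i][k] / b2t
                p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
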