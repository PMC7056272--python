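"""Minimal 1-D convolutional network engine (numpy, CPU).

Just enough machinery for the SWD candidate classifier: 1-D convolutions
(valid non-overlapping, or stride-1 same-padding), ReLU, max pooling,
global average pooling, dropout, a dense sigmoid head, binary cross
entropy and the Adadelta update rule. Forward passes cache what backward
needs; all state lives in the layer objects.
"""

from __future__ import annotations

import numpy as np


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    """1-D convolution over (batch, channels, length).

    ``stride == kernel`` gives non-overlapping (patch) convolution with a
    trailing remainder dropped; ``stride == 1`` uses same-padding so the
    length is preserved. Other strides are not needed here.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, rng: np.random.Generator):
        super().__init__()
        if stride not in (1, kernel):
            raise ValueError("stride must be 1 (same padding) or equal to kernel")
        self.k, self.stride = kernel, stride
        scale = np.sqrt(2.0 / (c_in * kernel))  # He initialization
        self.w = (rng.standard_normal((c_out, c_in, kernel)) * scale).astype(np.float64)
        self.b = np.zeros(c_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, training):
        if self.stride == self.k:
            lp = x.shape[2] // self.k
            cols = x[:, :, : lp * self.k].reshape(x.shape[0], x.shape[1], lp, self.k)
            self._cache = ("patch", cols, x.shape[2])
        else:
            p0 = self.k // 2
            xp = np.pad(x, ((0, 0), (0, 0), (p0, self.k - 1 - p0)))
            cols = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
            self._cache = ("same", cols, x.shape[2])
        return np.einsum("bclk,fck->bfl", cols, self.w, optimize=True) + self.b[None, :, None]

    def backward(self, dy):
        mode, cols, lx = self._cache
        self.grads[0][...] = np.einsum("bfl,bclk->fck", dy, cols, optimize=True)
        self.grads[1][...] = dy.sum(axis=(0, 2))
        if mode == "patch":
            dcols = np.einsum("bfl,fck->bclk", dy, self.w, optimize=True)
            dx = np.zeros((dy.shape[0], self.w.shape[1], lx))
            lp = dy.shape[2]
            dx[:, :, : lp * self.k] = dcols.reshape(dy.shape[0], self.w.shape[1], lp * self.k)
            return dx
        p0 = self.k // 2
        dxp = np.zeros((dy.shape[0], self.w.shape[1], lx + self.k - 1))
        for j in range(self.k):
            dxp[:, :, j : j + lx] += np.einsum("bfl,fc->bcl", dy, self.w[:, :, j], optimize=True)
        return dxp[:, :, p0 : p0 + lx]


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool1d(Layer):
    def __init__(self, factor: int):
        super().__init__()
        self.f = factor

    def forward(self, x, training):
        b, c, l = x.shape
        lp = l // self.f
        if lp < 1:
            raise ValueError(f"length {l} too short for pool factor {self.f}")
        r = x[:, :, : lp * self.f].reshape(b, c, lp, self.f)
        self._idx = r.argmax(axis=3)
        self._shape = x.shape
        return r.max(axis=3)

    def backward(self, dy):
        b, c, l = self._shape
        lp = dy.shape[2]
        dr = np.zeros((b, c, lp, self.f))
        np.put_along_axis(dr, self._idx[..., None], dy[..., None], axis=3)
        dx = np.zeros((b, c, l))
        dx[:, :, : lp * self.f] = dr.reshape(b, c, lp * self.f)
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x, training):
        self._l = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy):
        return np.repeat(dy[:, :, None], self._l, axis=2) / self._l


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p, self.rng = p, rng

    def forward(self, x, training):
        if not training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Dense(Layer):
    def __init__(self, c_in: int, rng: np.random.Generator):
        super().__init__()
        self.w = rng.standard_normal(c_in) * np.sqrt(1.0 / c_in)
        self.b = np.zeros(1)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, training):
        self._x = x
        return x @ self.w + self.b[0]

    def backward(self, dy):
        self.grads[0][...] = dy @ self._x
        self.grads[1][...] = dy.sum()
        return dy[:, None] * self.w[None, :]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross entropy and its gradient w.r.t. the logits."""
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    dz = (sigmoid(z) - y) / z.size
    return loss, dz


class Adadelta:
    """Adadelta update: parameter-wise adaptive steps, no learning rate."""

    def __init__(self, layers: list[Layer], rho: float = 0.95, eps: float = 1e-6):
        self.rho, self.eps = rho, eps
        self.layers = [l for l in layers if l.params]
        self._eg = [[np.zeros_like(p) for p in l.params] for l in self.layers]
        self._ex = [[np.zeros_like(p) for p in l.params] for l in self.layers]

    def step(self) -> None:
        for li, layer in enumerate(self.layers):
            for pi, (p, g) in enumerate(zip(layer.params, layer.grads)):
                eg, ex = self._eg[li][pi], self._ex[li][pi]
                eg *= self.rho
                eg += (1 - self.rho) * g**2
                dx = -np.sqrt(ex + self.eps) / np.sqrt(eg + self.eps) * g
                ex *= self.rho
                ex += (1 - self.rho) * dx**2
                p += dx


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                out[f"layer{i}.param{j}"] = p
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                p[...] = state[f"layer{i}.param{j}"]
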