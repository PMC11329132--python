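"""Minimal NumPy neural-network layers with hand-written backpropagation.

Implements exactly the primitives the conditional-GAN architecture needs
(strided 2D convolution, nearest-neighbour upsampling, instance
normalisation, the usual activations, binary cross-entropy on logits,
and Adam).  Convolutions run through an im2col/col2im pair so both the
forward and the adjoint are single BLAS matmuls.  Arrays are NCHW
float32; parameter initialisation is N(0, 0.02) from a seeded generator.

Layers follow a two-method contract::

    y  = layer.forward(x)    # caches what backward needs
    gx = layer.backward(gy)  # accumulates layer.grads, returns input grad
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Layer:
    """Base class: parameter-free identity."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k, p in self.params.items():
            if k in self.grads:
                self.grads[k].fill(0)
            else:
                self.grads[k] = np.zeros_like(p)


class Conv2d(Layer):
    """2D convolution (cross-correlation), arbitrary kernel/stride/pad."""

    def __init__(self, c_in: int, c_out: int, ksize: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None,
                 init_std: float = 0.02):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out = c_in, c_out
        self.k, self.stride, self.pad = ksize, stride, pad
        self.params = {
            "W": rng.normal(0.0, init_std, size=(c_out, c_in, ksize, ksize)).astype(DTYPE),
            "b": np.zeros(c_out, dtype=DTYPE),
        }
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        n, c, h, w = x.shape
        if (h + 2 * p - k) % s or (w + 2 * p - k) % s:
            raise ValueError(
                f"spatial size {(h, w)} incompatible with kernel {k}, "
                f"stride {s}, pad {p}"
            )
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * k * k)
        wmat = self.params["W"].reshape(self.c_out, -1)
        y = cols @ wmat.T + self.params["b"]
        self._cache = (cols, x.shape, xp.shape, ho, wo)
        return np.ascontiguousarray(
            y.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols, x_shape, xp_shape, ho, wo = self._cache
        n, c, h, w = x_shape
        k, s, p = self.k, self.stride, self.pad
        gmat = np.ascontiguousarray(gy.transpose(0, 2, 3, 1)).reshape(-1, self.c_out)
        self.grads["W"] += (gmat.T @ cols).reshape(self.params["W"].shape)
        self.grads["b"] += gmat.sum(axis=0)
        gcols = (gmat @ self.params["W"].reshape(self.c_out, -1)).reshape(
            n, ho, wo, c, k, k)
        gxp = np.zeros(xp_shape, dtype=DTYPE)
        for di in range(k):
            for dj in range(k):
                gxp[:, :, di:di + s * ho:s, dj:dj + s * wo:s] += \
                    gcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return gxp[:, :, p:p + h, p:p + w] if p else gxp


class UpsampleNearest(Layer):
    """2x nearest-neighbour upsampling; adjoint sums 2x2 blocks."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = gy.shape
        return gy.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))


class InstanceNorm2d(Layer):
    """Per-sample, per-channel normalisation over the spatial axes.

    At batch size 1 this matches train-mode batch normalisation.  A 1x1
    spatial extent (U-Net bottleneck) is degenerate and passes through
    unchanged.
    """

    def __init__(self, c: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.params = {"gamma": np.ones(c, dtype=DTYPE), "beta": np.zeros(c, dtype=DTYPE)}
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[2] * x.shape[3] == 1:
            self._cache = None
            return x
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv.astype(DTYPE))
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        return (g * xhat + b).astype(DTYPE)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._cache is None:
            return gy
        xhat, inv = self._cache
        self.grads["gamma"] += (gy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += gy.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        gxhat = gy * g
        m1 = gxhat.mean(axis=(2, 3), keepdims=True)
        m2 = (gxhat * xhat).mean(axis=(2, 3), keepdims=True)
        return ((gxhat - m1 - xhat * m2) * inv).astype(DTYPE)


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        super().__init__()
        self.alpha = alpha

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, self.alpha * gy)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(alpha=0.0)


class Tanh(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * (1.0 - self._y * self._y)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def named_params(self, prefix: str = ""):
        for i, layer in enumerate(self.layers):
            if isinstance(layer, Sequential):
                yield from layer.named_params(f"{prefix}{i}.")
            else:
                for k in layer.params:
                    yield f"{prefix}{i}.{k}", layer, k


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def bce_with_logits(z: np.ndarray, target: float) -> float:
    """Mean binary cross-entropy of a logit grid against a constant label."""
    z = np.asarray(z, dtype=np.float64)
    return float(np.mean(np.maximum(z, 0.0) - z * target + np.log1p(np.exp(-np.abs(z)))))


def bce_with_logits_grad(z: np.ndarray, target: float) -> np.ndarray:
    """d(mean BCE)/dz = (sigmoid(z) - target) / n."""
    z64 = np.asarray(z, dtype=np.float64)
    sig = 1.0 / (1.0 + np.exp(-z64))
    return ((sig - target) / z.size).astype(DTYPE)


def l1_loss(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean(np.abs(np.asarray(a, dtype=np.float64)
                                - np.asarray(b, dtype=np.float64))))


def l1_loss_grad(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """d(mean |a-b|)/da, subgradient 0 at ties."""
    return (np.sign(a - b) / a.size).astype(DTYPE)


# ---------------------------------------------------------------------------
# Optimiser
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the bias-corrected update (pix2pix defaults elsewhere)."""

    def __init__(self, model, lr: float = 2e-4, beta1: float = 0.5,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.slots = list(model.named_params())
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(layer.params[k]) for _, layer, k in self.slots]
        self.v = [np.zeros_like(layer.params[k]) for _, layer, k in self.slots]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for i, (_, layer, k) in enumerate(self.slots):
            g = layer.grads[k]
            m, v = self.m[i], self.v[i]
            # in-place first/second moment updates
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            denom = np.sqrt(v / c2)
            denom += self.eps
            layer.params[k] -= (self.lr / c1) * m / denom


def state_dict(model) -> dict[str, np.ndarray]:
    return {name: layer.params[k].copy() for name, layer, k in model.named_params()}


def load_state_dict(model, state: dict[str, np.ndarray]) -> None:
    for name, layer, k in model.named_params():
        layer.params[k] = np.asarray(state[name], dtype=DTYPE).copy()
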