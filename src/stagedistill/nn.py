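"""Minimal differentiable layer kit in NumPy.

Just enough machinery to train the miniature four-stage convolutional
backbones used for desk-scale distillation experiments: strided 2-D
convolution (im2col), ReLU, global average pooling, a linear head, a
sequential container, and a decoupled-weight-decay Adam optimizer. All
arithmetic is float32 and fully deterministic, so two runs with the same
seed and data produce bitwise-identical results.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "ReLU",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
    "AdamW",
]

DTYPE = np.float32


class Layer:
    """Base class: forward caches whatever backward needs."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def zero_grad(self) -> None:
        for g in self.grads().values():
            g[...] = 0.0


class Conv2d(Layer):
    """2-D convolution with square kernel, implemented via im2col.

    Weights use He-normal initialization (appropriate for the ReLU
    nonlinearity that follows every convolution here).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        padding: int = 1,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = (rng.standard_normal(
            (out_channels, in_channels, kernel_size, kernel_size)
        ) * std).astype(DTYPE)
        self.bias = np.zeros(out_channels, dtype=DTYPE)
        self.grad_weight = np.zeros_like(self.weight)
        self.grad_bias = np.zeros_like(self.bias)
        self.stride = stride
        self.padding = padding
        self.kernel_size = kernel_size
        self._cache: tuple | None = None

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        k, s, p = self.kernel_size, self.stride, self.padding
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        windows = windows[:, :, ::s, ::s]  # (B, C, Ho, Wo, k, k)
        return windows, x.shape

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        windows, padded_shape = self._im2col(x)
        b, c, ho, wo, k, _ = windows.shape
        col = windows.transpose(0, 2, 3, 1, 4, 5).reshape(b * ho * wo, c * k * k)
        wmat = self.weight.reshape(self.weight.shape[0], -1)
        out = col @ wmat.T + self.bias
        out = out.reshape(b, ho, wo, -1).transpose(0, 3, 1, 2)
        self._cache = (col, x.shape, padded_shape, (b, ho, wo))
        return np.ascontiguousarray(out)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        col, x_shape, padded_shape, (b, ho, wo) = self._cache
        k, s, p = self.kernel_size, self.stride, self.padding
        g = grad_out.transpose(0, 2, 3, 1).reshape(b * ho * wo, -1)
        wmat = self.weight.reshape(self.weight.shape[0], -1)
        self.grad_weight += (g.T @ col).reshape(self.weight.shape)
        self.grad_bias += g.sum(axis=0)
        gcol = g @ wmat  # (B*Ho*Wo, C*k*k)
        gcol = gcol.reshape(b, ho, wo, x_shape[1], k, k)
        gx_pad = np.zeros(padded_shape, dtype=DTYPE)
        for ki in range(k):
            for kj in range(k):
                gx_pad[:, :, ki : ki + ho * s : s, kj : kj + wo * s : s] += (
                    gcol[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
                )
        if p:
            return gx_pad[:, :, p:-p, p:-p]
        return gx_pad

    def params(self) -> dict[str, np.ndarray]:
        return {"weight": self.weight, "bias": self.bias}

    def grads(self) -> dict[str, np.ndarray]:
        return {"weight": self.grad_weight, "bias": self.grad_bias}


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(DTYPE)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad_out, 0).astype(DTYPE)


class GlobalAvgPool(Layer):
    """(B, C, H, W) -> (B, C) spatial mean."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3), dtype=DTYPE)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        g = grad_out[:, :, None, None] / (h * w)
        return np.broadcast_to(g, self._shape).astype(DTYPE)


class Linear(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / in_features)
        self.weight = (rng.standard_normal((out_features, in_features)) * std).astype(DTYPE)
        self.bias = np.zeros(out_features, dtype=DTYPE)
        self.grad_weight = np.zeros_like(self.weight)
        self.grad_bias = np.zeros_like(self.bias)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = np.asarray(x, dtype=DTYPE)
        return self._x @ self.weight.T + self.bias

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        g = np.asarray(grad_out, dtype=DTYPE)
        self.grad_weight += g.T @ self._x
        self.grad_bias += g.sum(axis=0)
        return g @ self.weight

    def params(self) -> dict[str, np.ndarray]:
        return {"weight": self.weight, "bias": self.bias}

    def grads(self) -> dict[str, np.ndarray]:
        return {"weight": self.grad_weight, "bias": self.grad_bias}


class Sequential(Layer):
    """Ordered, named composition of layers."""

    def __init__(self, layers: Iterable[tuple[str, Layer]] = ()) -> None:
        self.layers: list[tuple[str, Layer]] = list(layers)
        names = [n for n, _ in self.layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")

    def add(self, name: str, layer: Layer) -> None:
        if any(n == name for n, _ in self.layers):
            raise ValueError(f"duplicate layer name {name!r}")
        self.layers.append((name, layer))

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.layers]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for _, layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for _, layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    def params(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, layer in self.layers:
            for pname, p in layer.params().items():
                out[f"{name}.{pname}"] = p
        return out

    def grads(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, layer in self.layers:
            for gname, g in layer.grads().items():
                out[f"{name}.{gname}"] = g
        return out

    def slice(self, names: list[str]) -> "Sequential":
        """Sub-network holding the listed layers (shared, not copied)."""
        table = dict(self.layers)
        return Sequential([(n, table[n]) for n in names])


def set_params(layer: Layer, values: dict[str, np.ndarray]) -> None:
    """Copy ``values`` into a layer's parameter arrays, by name."""
    params = layer.params()
    missing = set(params) - set(values)
    if missing:
        raise KeyError(f"missing parameters: {sorted(missing)}")
    for name, p in params.items():
        v = np.asarray(values[name], dtype=p.dtype)
        if v.shape != p.shape:
            raise ValueError(f"shape mismatch for {name}: {v.shape} vs {p.shape}")
        p[...] = v


class AdamW:
    """Adam with decoupled weight decay.

    ``betas[0]`` plays the role of classical momentum (first-moment
    decay); weight decay is applied multiplicatively to the parameters,
    not through the gradient, and is skipped for 1-D parameters
    (biases), the usual convention.
    """

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 5e-4,
    ) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            g = grads[k].astype(p.dtype)
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            if self.weight_decay and p.ndim > 1:
                p *= 1.0 - self.lr * self.weight_decay
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)
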