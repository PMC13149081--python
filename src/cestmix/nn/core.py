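"""Compact numpy neural-network library: modules with explicit backprop.

All layers operate on channels-last tensors ``(B, H, W, C)`` (or ``(N, C)``
for dense layers).  Each module caches what its backward pass needs during
``forward`` and releases gradients into per-parameter ``.grad`` buffers on
``backward``.  Single-threaded, float32 throughout.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np
from scipy.special import ndtr  # standard normal CDF

DTYPE = np.float32
_SQRT_2PI = float(np.sqrt(2.0 * np.pi))


class Param:
    """A trainable tensor with its gradient buffer."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)


class Module:
    """Base class; children are discovered by attribute scan (insertion order)."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.forward(x, train=train)

    # -- parameter bookkeeping ------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Param]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Param):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")

    def parameters(self) -> list[Param]:
        return [p for _, p in self.named_parameters()]

    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state dict mismatch: {sorted(missing)[:5]} ...")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data[...] = state[name]


def _he(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Linear(Module):
    """Dense map on the last axis: ``y = x W + b`` (also a 1x1 convolution)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.W = Param(_he(rng, (c_in, c_out), c_in))
        self.b = Param(np.zeros(c_out))

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x if train else None
        return x @ self.W.data + self.b.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self.W.data.shape[0])
        dy2 = dy.reshape(-1, self.W.data.shape[1])
        self.W.grad += x2.T @ dy2
        self.b.grad += dy2.sum(axis=0)
        return dy @ self.W.data.T


class DepthwiseConv3x3(Module):
    """Per-channel 3x3 convolution, same padding; channels never mix."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.W = Param(_he(rng, (3, 3, channels), 9))
        self.b = Param(np.zeros(channels))

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, H, Wd, C = x.shape
        xp = np.zeros((B, H + 2, Wd + 2, C), dtype=x.dtype)
        xp[:, 1:-1, 1:-1] = x
        self._xp = xp if train else None
        self._shape = (B, H, Wd, C)
        y = np.empty_like(x)
        y[...] = self.b.data
        for i in range(3):
            for j in range(3):
                y += xp[:, i : i + H, j : j + Wd] * self.W.data[i, j]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, H, Wd, C = self._shape
        dxp = np.zeros_like(self._xp)
        for i in range(3):
            for j in range(3):
                self.W.grad[i, j] += np.einsum(
                    "bhwc,bhwc->c", self._xp[:, i : i + H, j : j + Wd], dy
                )
                dxp[:, i : i + H, j : j + Wd] += dy * self.W.data[i, j]
        self.b.grad += dy.sum(axis=(0, 1, 2))
        return dxp[:, 1:-1, 1:-1]


class Conv3x3(Module):
    """Full 3x3 convolution, same padding (im2col)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.W = Param(_he(rng, (9 * c_in, c_out), 9 * c_in))
        self.b = Param(np.zeros(c_out))
        self._c_in = c_in

    def _cols(self, xp: np.ndarray, H: int, Wd: int) -> np.ndarray:
        v = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
        # (B, H, W, C, 3, 3) -> (B, H, W, 3, 3, C)
        return np.ascontiguousarray(v.transpose(0, 1, 2, 4, 5, 3))

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, H, Wd, C = x.shape
        xp = np.zeros((B, H + 2, Wd + 2, C), dtype=x.dtype)
        xp[:, 1:-1, 1:-1] = x
        cols = self._cols(xp, H, Wd).reshape(B * H * Wd, 9 * C)
        self._cols_cache = cols if train else None
        self._shape = (B, H, Wd, C)
        y = cols @ self.W.data + self.b.data
        return y.reshape(B, H, Wd, -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, H, Wd, C = self._shape
        c_out = self.W.data.shape[1]
        dy2 = dy.reshape(-1, c_out)
        self.W.grad += self._cols_cache.T @ dy2
        self.b.grad += dy2.sum(axis=0)
        dcols = (dy2 @ self.W.data.T).reshape(B, H, Wd, 3, 3, C)
        dxp = np.zeros((B, H + 2, Wd + 2, C), dtype=dy.dtype)
        for i in range(3):
            for j in range(3):
                dxp[:, i : i + H, j : j + Wd] += dcols[:, :, :, i, j]
        return dxp[:, 1:-1, 1:-1]


class LayerNorm(Module):
    """Normalization over the channel axis, per spatial position."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.g = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc**2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = xc * inv
        if train:
            self._xhat, self._inv = xhat, inv
        return xhat * self.g.data + self.beta.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        C = xhat.shape[-1]
        self.g.grad += np.sum(dy * xhat, axis=tuple(range(dy.ndim - 1)))
        self.beta.grad += np.sum(dy, axis=tuple(range(dy.ndim - 1)))
        dxhat = dy * self.g.data
        return inv * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        )


class GELU(Module):
    """Exact Gaussian-error linear unit, ``x * Phi(x)``."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        phi = ndtr(x).astype(x.dtype)
        if train:
            self._x, self._phi = x, phi
        return x * phi

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        pdf = np.exp(-0.5 * x * x) / _SQRT_2PI
        return dy * (self._phi + x * pdf)


class Sigmoid(Module):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class Softmax(Module):
    """Softmax over the channel axis."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=-1, keepdims=True)
        if train:
            self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        y = self._y
        return y * (dy - (dy * y).sum(axis=-1, keepdims=True))


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.layers = list(modules)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for m in self.layers:
            x = m.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for m in reversed(self.layers):
            dy = m.backward(dy)
        return dy


class SpaceToDepthDown(Module):
    """2x spatial downsampling: 2x2 blocks folded to channels, then dense mix.

    Equivalent to a 2x2 stride-2 convolution.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.proj = Linear(4 * c_in, c_out, rng)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, H, W, C = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"downsample needs even extent, got {(H, W)}")
        self._shape = (B, H, W, C)
        folded = (
            x.reshape(B, H // 2, 2, W // 2, 2, C)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(B, H // 2, W // 2, 4 * C)
        )
        return self.proj.forward(folded, train=train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, H, W, C = self._shape
        dfolded = self.proj.backward(dy)
        return (
            dfolded.reshape(B, H // 2, W // 2, 2, 2, C)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(B, H, W, C)
        )


class DepthToSpaceUp(Module):
    """2x spatial upsampling: dense mix to 4x channels, unfolded to 2x2 blocks.

    Equivalent to a 2x2 stride-2 transposed convolution.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.proj = Linear(c_in, 4 * c_out, rng)
        self._c_out = c_out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, H, W, _ = x.shape
        y = self.proj.forward(x, train=train)
        return (
            y.reshape(B, H, W, 2, 2, self._c_out)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(B, 2 * H, 2 * W, self._c_out)
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, H2, W2, C = dy.shape
        H, W = H2 // 2, W2 // 2
        dfold = (
            dy.reshape(B, H, 2, W, 2, C)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(B, H, W, 4 * C)
        )
        return self.proj.backward(dfold)


class SGD:
    """Stochastic gradient descent with momentum and decoupled weight decay."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v -= self.lr * g
            p.data += v
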