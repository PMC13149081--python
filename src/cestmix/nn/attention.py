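"""Window-based multi-head self-attention (W-MSA).

Attention is computed independently inside non-overlapping ``win x win``
spatial windows, so no information crosses window boundaries.  Feature maps
whose extent is not a multiple of the window are zero-padded and the output
cropped back, restoring the input extent exactly.
"""

from __future__ import annotations

import numpy as np

from .core import Linear, Module


def pad_to_multiple(x: np.ndarray, m: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Zero-pad the two spatial axes of (B, H, W, C) up to multiples of m."""
    B, H, W, C = x.shape
    ph = (-H) % m
    pw = (-W) % m
    if ph == 0 and pw == 0:
        return x, (0, 0)
    out = np.zeros((B, H + ph, W + pw, C), dtype=x.dtype)
    out[:, :H, :W] = x
    return out, (ph, pw)


def window_partition(x: np.ndarray, win: int) -> np.ndarray:
    """(B, H, W, C) -> (B*nH*nW, win*win, C); H, W must be multiples of win."""
    B, H, W, C = x.shape
    if H % win or W % win:
        raise ValueError(f"spatial extent {(H, W)} not divisible by window {win}")
    t = x.reshape(B, H // win, win, W // win, win, C)
    return t.transpose(0, 1, 3, 2, 4, 5).reshape(-1, win * win, C)


def window_reverse(tiles: np.ndarray, win: int, shape: tuple[int, int, int, int]) -> np.ndarray:
    """Exact inverse of :func:`window_partition`."""
    B, H, W, C = shape
    t = tiles.reshape(B, H // win, W // win, win, win, C)
    return t.transpose(0, 1, 3, 2, 4, 5).reshape(B, H, W, C)


class WindowAttention(Module):
    """Scaled dot-product multi-head self-attention within local windows."""

    def __init__(self, channels: int, window: int, heads: int, rng: np.random.Generator):
        if channels % heads:
            raise ValueError(f"channels {channels} not divisible by heads {heads}")
        self.window = window
        self.heads = heads
        self.channels = channels
        self.qkv = Linear(channels, 3 * channels, rng)
        self.proj = Linear(channels, channels, rng)

    # -- tile-level attention -------------------------------------------------
    def _attend(self, tiles: np.ndarray, train: bool) -> np.ndarray:
        N, T, C = tiles.shape
        h, d = self.heads, C // self.heads
        qkv = self.qkv.forward(tiles, train=train)  # (N, T, 3C)
        q, k, v = np.split(qkv, 3, axis=-1)
        q = q.reshape(N, T, h, d).transpose(0, 2, 1, 3)  # (N, h, T, d)
        k = k.reshape(N, T, h, d).transpose(0, 2, 1, 3)
        v = v.reshape(N, T, h, d).transpose(0, 2, 1, 3)
        scale = 1.0 / np.sqrt(d)
        s = (q @ k.transpose(0, 1, 3, 2)) * scale  # (N, h, T, T)
        s -= s.max(axis=-1, keepdims=True)
        e = np.exp(s)
        a = e / e.sum(axis=-1, keepdims=True)
        o = a @ v  # (N, h, T, d)
        out = o.transpose(0, 2, 1, 3).reshape(N, T, C)
        if train:
            self._cache = (q, k, v, a, scale, (N, T, C))
        return self.proj.forward(out, train=train)

    def _attend_backward(self, dout: np.ndarray) -> np.ndarray:
        q, k, v, a, scale, (N, T, C) = self._cache
        h, d = self.heads, C // self.heads
        do = self.proj.backward(dout)
        do = do.reshape(N, T, h, d).transpose(0, 2, 1, 3)  # (N, h, T, d)
        dv = a.transpose(0, 1, 3, 2) @ do
        da = do @ v.transpose(0, 1, 3, 2)  # (N, h, T, T)
        ds = a * (da - (da * a).sum(axis=-1, keepdims=True))
        dq = (ds @ k) * scale
        dk = (ds.transpose(0, 1, 3, 2) @ q) * scale
        dqkv = np.concatenate(
            [
                dq.transpose(0, 2, 1, 3).reshape(N, T, C),
                dk.transpose(0, 2, 1, 3).reshape(N, T, C),
                dv.transpose(0, 2, 1, 3).reshape(N, T, C),
            ],
            axis=-1,
        )
        return self.qkv.backward(dqkv)

    # -- map-level wrapper ----------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, H, W, C = x.shape
        xp, (ph, pw) = pad_to_multiple(x, self.window)
        self._pad_shape = (xp.shape, (H, W))
        tiles = window_partition(xp, self.window)
        out = self._attend(tiles, train)
        y = window_reverse(out, self.window, xp.shape)
        return y[:, :H, :W]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        (pshape, (H, W)) = self._pad_shape
        dpad = np.zeros(pshape, dtype=dy.dtype)
        dpad[:, :H, :W] = dy
        dtiles = window_partition(dpad, self.window)
        dx_tiles = self._attend_backward(dtiles)
        dxp = window_reverse(dx_tiles, self.window, pshape)
        return dxp[:, :H, :W]
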