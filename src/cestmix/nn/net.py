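"""The dual-branch Mixing Block and the U-Net-shaped network built from it.

Each Mixing Block runs a window-attention branch and a depthwise-convolution
branch in parallel on the same (layer-normalized) input.  With bi-directional
interactions enabled, the conv branch emits a per-channel sigmoid gate
(global average pool -> bottleneck 1x1 -> sigmoid) applied to the attention
output, and the attention branch emits a per-pixel sigmoid gate
(channel-reducing 1x1 -> sigmoid) applied to the conv output.  Branch outputs
are concatenated and fused by a two-layer GELU feed-forward network back to
the stage width; a residual connection wraps the whole block.

The network is a four-stage encoder/decoder: Mixing-Block stacks with
progressive 2x downsampling and channel doubling in the encoder, transposed-
convolution upsampling with skip concatenation and plain double-convolution
blocks in the decoder (a placement switch puts Mixing Blocks in the decoder
too), and a 1x1-convolution softmax head emitting N per-pixel class
probabilities at input resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attention import WindowAttention
from .core import (
    GELU,
    Conv3x3,
    DepthToSpaceUp,
    DepthwiseConv3x3,
    LayerNorm,
    Linear,
    Module,
    Sequential,
    Sigmoid,
    Softmax,
    SpaceToDepthDown,
)


@dataclass
class NetworkConfig:
    """Architectural description from which every variant is built.

    ``base_width`` sets stage widths ``(w, 2w, 4w, 8w)``; ``literal_widths``
    instead uses ``(2C, 4C, 8C, 16C)`` with C the input channel count (the
    stated channel-expansion rule read literally).  Heads per stage default
    to ``max(1, width // 16)``.
    """

    in_channels: int = 41
    n_classes: int = 2
    base_width: int = 32
    literal_widths: bool = False
    depths: tuple[int, int, int, int] = (2, 2, 4, 2)
    window: int = 4
    heads: tuple[int, int, int, int] | None = None
    ffn_ratio: int = 4
    conv_branch: bool = True
    attn_branch: bool = True
    interactions: bool = True
    reverse_interactions: bool = False
    placement: str = "encoder_only"  # or "encoder_and_decoder"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.depths) != 4:
            raise ValueError("exactly four stage depths required")
        if not (self.conv_branch or self.attn_branch):
            raise ValueError("at least one branch must be enabled")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.placement not in ("encoder_only", "encoder_and_decoder"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.interactions and not (self.conv_branch and self.attn_branch):
            self.interactions = False  # gates need both branches

    def stage_widths(self) -> tuple[int, int, int, int]:
        if self.literal_widths:
            c = self.in_channels
            return (2 * c, 4 * c, 8 * c, 16 * c)
        w = self.base_width
        return (w, 2 * w, 4 * w, 8 * w)

    def stage_heads(self) -> tuple[int, ...]:
        if self.heads is not None:
            return tuple(self.heads)
        return tuple(max(1, w // 16) for w in self.stage_widths())

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["depths"] = list(self.depths)
        if d["heads"] is not None:
            d["heads"] = list(d["heads"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["depths"] = tuple(d["depths"])
        if d.get("heads") is not None:
            d["heads"] = tuple(d["heads"])
        return cls(**d)


class ChannelInteraction(Module):
    """Per-channel gate from the source branch: GAP -> bottleneck 1x1 -> sigmoid."""

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 4):
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden, rng)
        self.act = GELU()
        self.fc2 = Linear(hidden, channels, rng)
        self.sig = Sigmoid()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, H, W, C = x.shape
        self._hw = (H, W)
        m = x.mean(axis=(1, 2))  # (B, C)
        g = self.sig.forward(
            self.fc2.forward(self.act.forward(self.fc1.forward(m, train), train), train),
            train,
        )
        return g[:, None, None, :]  # broadcastable gate

    def backward(self, dg: np.ndarray) -> np.ndarray:
        H, W = self._hw
        dm = self.fc1.backward(
            self.act.backward(self.fc2.backward(self.sig.backward(dg[:, 0, 0, :])))
        )
        return np.broadcast_to(dm[:, None, None, :] / (H * W), (dm.shape[0], H, W, dm.shape[1])).copy()


class SpatialInteraction(Module):
    """Per-pixel gate from the source branch: channel-reducing 1x1 -> sigmoid."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.fc = Linear(channels, 1, rng)
        self.sig = Sigmoid()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.sig.forward(self.fc.forward(x, train), train)  # (B, H, W, 1)

    def backward(self, dg: np.ndarray) -> np.ndarray:
        return self.fc.backward(self.sig.backward(dg))


class FFN(Module):
    """Pixel-wise two-layer transform with GELU, restoring the stage width."""

    def __init__(self, c_in: int, c_out: int, ratio: int, rng: np.random.Generator):
        hidden = ratio * c_out
        self.net = Sequential(Linear(c_in, hidden, rng), GELU(), Linear(hidden, c_out, rng))

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.net.forward(x, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.net.backward(dy)


class MixingBlock(Module):
    """Parallel W-MSA / depthwise-conv branches with optional gating, FFN fusion
    and a residual connection.  Output shape equals input shape."""

    def __init__(self, channels: int, window: int, heads: int, ffn_ratio: int,
                 conv_branch: bool, attn_branch: bool, interactions: bool,
                 reverse_interactions: bool, rng: np.random.Generator):
        if not (conv_branch or attn_branch):
            raise ValueError("at least one branch must be enabled")
        self.use_conv = conv_branch
        self.use_attn = attn_branch
        self.use_inter = interactions and conv_branch and attn_branch
        self.reverse = reverse_interactions
        self.norm = LayerNorm(channels)
        if attn_branch:
            self.attn = WindowAttention(channels, window, heads, rng)
        if conv_branch:
            self.conv = DepthwiseConv3x3(channels, rng)
        if self.use_inter:
            self.ch_gate = ChannelInteraction(channels, rng)
            self.sp_gate = SpatialInteraction(channels, rng)
        width_in = channels * (2 if (conv_branch and attn_branch) else 1)
        self.ffn = FFN(width_in, channels, ffn_ratio, rng)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        xn = self.norm.forward(x, train)
        a = self.attn.forward(xn, train) if self.use_attn else None
        c = self.conv.forward(xn, train) if self.use_conv else None
        if self.use_inter:
            if not self.reverse:
                gch = self.ch_gate.forward(c, train)   # conv -> channel gate on attn
                gsp = self.sp_gate.forward(a, train)   # attn -> spatial gate on conv
                a2, c2 = a * gch, c * gsp
            else:
                gch = self.ch_gate.forward(a, train)
                gsp = self.sp_gate.forward(c, train)
                a2, c2 = a * gsp, c * gch
            if train:
                self._gates = (a, c, gch, gsp)
        else:
            a2, c2 = a, c
            if train:
                self._gates = (a, c, None, None)
        if a2 is not None and c2 is not None:
            h = np.concatenate([a2, c2], axis=-1)
        else:
            h = a2 if a2 is not None else c2
        return x + self.ffn.forward(h, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.ffn.backward(dy)
        a, c, gch, gsp = self._gates
        if self.use_attn and self.use_conv:
            C = a.shape[-1]
            da2, dc2 = dh[..., :C], dh[..., C:]
        elif self.use_attn:
            da2, dc2 = dh, None
        else:
            da2, dc2 = None, dh
        if self.use_inter:
            if not self.reverse:
                da = da2 * gch
                dgch = (da2 * a).sum(axis=(1, 2), keepdims=True)
                dc = dc2 * gsp
                dgsp = (dc2 * c).sum(axis=-1, keepdims=True)
                dc_gate = self.ch_gate.backward(dgch)
                da_gate = self.sp_gate.backward(dgsp)
                da_tot, dc_tot = da + da_gate, dc + dc_gate
            else:
                da = da2 * gsp
                dgsp = (da2 * a).sum(axis=-1, keepdims=True)
                dc = dc2 * gch
                dgch = (dc2 * c).sum(axis=(1, 2), keepdims=True)
                da_gate = self.ch_gate.backward(dgch)
                dc_gate = self.sp_gate.backward(dgsp)
                da_tot, dc_tot = da + da_gate, dc + dc_gate
        else:
            da_tot, dc_tot = da2, dc2
        dxn = None
        if self.use_attn:
            dxn = self.attn.backward(da_tot)
        if self.use_conv:
            dconv = self.conv.backward(dc_tot)
            dxn = dconv if dxn is None else dxn + dconv
        return dy + self.norm.backward(dxn)


class DoubleConv(Module):
    """Decoder block: two (3x3 conv -> LayerNorm -> GELU) layers."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.net = Sequential(
            Conv3x3(c_in, c_out, rng), LayerNorm(c_out), GELU(),
            Conv3x3(c_out, c_out, rng), LayerNorm(c_out), GELU(),
        )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.net.forward(x, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.net.backward(dy)


class MixBranchNet(Module):
    """Four-stage encoder/decoder with Mixing-Block stages and a softmax head.

    Input ``(B, H, W, C_in)`` with H, W divisible by 8 (three downsamplings);
    output ``(B, H, W, N)`` per-pixel class probabilities summing to 1.
    """

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        w = config.stage_widths()
        heads = config.stage_heads()
        d = config.depths

        def stage(width: int, depth: int, head: int) -> Sequential:
            return Sequential(*[
                MixingBlock(
                    width, config.window, head, config.ffn_ratio,
                    config.conv_branch, config.attn_branch,
                    config.interactions, config.reverse_interactions, rng,
                )
                for _ in range(depth)
            ])

        self.stem = Linear(config.in_channels, w[0], rng)
        self.enc0 = stage(w[0], d[0], heads[0])
        self.down0 = SpaceToDepthDown(w[0], w[1], rng)
        self.enc1 = stage(w[1], d[1], heads[1])
        self.down1 = SpaceToDepthDown(w[1], w[2], rng)
        self.enc2 = stage(w[2], d[2], heads[2])
        self.down2 = SpaceToDepthDown(w[2], w[3], rng)
        self.enc3 = stage(w[3], d[3], heads[3])

        def dec_block(c_in: int, c_out: int) -> Module:
            if config.placement == "encoder_and_decoder":
                return Sequential(Linear(c_in, c_out, rng),
                                  stage(c_out, 1, max(1, c_out // 16)))
            return DoubleConv(c_in, c_out, rng)

        self.up2 = DepthToSpaceUp(w[3], w[2], rng)
        self.dec2 = dec_block(2 * w[2], w[2])
        self.up1 = DepthToSpaceUp(w[2], w[1], rng)
        self.dec1 = dec_block(2 * w[1], w[1])
        self.up0 = DepthToSpaceUp(w[1], w[0], rng)
        self.dec0 = dec_block(2 * w[0], w[0])
        self.head = Linear(w[0], config.n_classes, rng)
        self.softmax = Softmax()

    # -- forward/backward -----------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, H, W, _ = x.shape
        if H % 8 or W % 8:
            raise ValueError(f"input extent {(H, W)} must be divisible by 8")
        s = self.stem.forward(x, train)
        e0 = self.enc0.forward(s, train)
        e1 = self.enc1.forward(self.down0.forward(e0, train), train)
        e2 = self.enc2.forward(self.down1.forward(e1, train), train)
        e3 = self.enc3.forward(self.down2.forward(e2, train), train)
        u2 = np.concatenate([self.up2.forward(e3, train), e2], axis=-1)
        d2 = self.dec2.forward(u2, train)
        u1 = np.concatenate([self.up1.forward(d2, train), e1], axis=-1)
        d1 = self.dec1.forward(u1, train)
        u0 = np.concatenate([self.up0.forward(d1, train), e0], axis=-1)
        d0 = self.dec0.forward(u0, train)
        return self.softmax.forward(self.head.forward(d0, train), train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        w = self.config.stage_widths()
        dd0 = self.head.backward(self.softmax.backward(dy))
        du0 = self.dec0.backward(dd0)
        dup0, de0_skip = du0[..., : w[0]], du0[..., w[0] :]
        dd1 = self.up0.backward(dup0)
        du1 = self.dec1.backward(dd1)
        dup1, de1_skip = du1[..., : w[1]], du1[..., w[1] :]
        dd2 = self.up1.backward(dup1)
        du2 = self.dec2.backward(dd2)
        dup2, de2_skip = du2[..., : w[2]], du2[..., w[2] :]
        de3 = self.up2.backward(dup2)
        de2 = self.enc3.backward(de3)
        de2 = self.down2.backward(de2) + de2_skip
        de1 = self.enc2.backward(de2)
        de1 = self.down1.backward(de1) + de1_skip
        de0 = self.enc1.backward(de1)
        de0 = self.down0.backward(de0) + de0_skip
        ds = self.enc0.backward(de0)
        return self.stem.backward(ds)


def build_network(config: NetworkConfig) -> MixBranchNet:
    """Construct a network (full model, ablation, or baseline) from a config."""
    return MixBranchNet(config)
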