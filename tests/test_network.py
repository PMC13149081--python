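"""Network building blocks: windows, attention, gates, blocks, full model."""

import numpy as np
import pytest
from scipy import ndimage

from cestmix.nn.attention import WindowAttention, window_partition, window_reverse
from cestmix.nn.core import SGD, DepthwiseConv3x3
from cestmix.nn.net import (
    ChannelInteraction,
    MixingBlock,
    NetworkConfig,
    SpatialInteraction,
    build_network,
)


class TestWindowPartition:
    def test_8x8_gives_four_tiles(self, rng):
        x = rng.normal(size=(1, 8, 8, 3)).astype(np.float32)
        tiles = window_partition(x, 4)
        assert tiles.shape == (4, 16, 3)
        np.testing.assert_array_equal(window_reverse(tiles, 4, x.shape), x)

    def test_4x4_single_tile_is_the_map(self, rng):
        x = rng.normal(size=(1, 4, 4, 2)).astype(np.float32)
        tiles = window_partition(x, 4)
        np.testing.assert_array_equal(tiles[0].reshape(4, 4, 2), x[0])

    def test_non_divisible_map_is_padded_and_restored(self, rng):
        attn = WindowAttention(8, window=4, heads=2, rng=np.random.default_rng(0))
        x = rng.normal(size=(2, 6, 6, 8)).astype(np.float32)
        out = attn.forward(x, train=False)
        assert out.shape == x.shape


class TestWMSA:
    def _dense_oracle(self, attn: WindowAttention, tile: np.ndarray) -> np.ndarray:
        """Independent dense computation: softmax(Q K^T / sqrt(d)) V."""
        C = attn.channels
        qkv = tile @ attn.qkv.W.data + attn.qkv.b.data
        q, k, v = qkv[:, :C], qkv[:, C : 2 * C], qkv[:, 2 * C :]
        h, d = attn.heads, C // attn.heads
        out = np.zeros_like(tile)
        for head in range(h):
            sl = slice(head * d, (head + 1) * d)
            s = q[:, sl] @ k[:, sl].T / np.sqrt(d)
            e = np.exp(s - s.max(axis=1, keepdims=True))
            a = e / e.sum(axis=1, keepdims=True)
            out[:, sl] = a @ v[:, sl]
        return out @ attn.proj.W.data + attn.proj.b.data

    def test_matches_dense_attention_oracle(self, rng):
        for heads in (1, 2):
            attn = WindowAttention(8, window=4, heads=heads, rng=np.random.default_rng(3))
            x = rng.normal(size=(1, 4, 4, 8)).astype(np.float32)
            got = attn.forward(x, train=False)[0].reshape(16, 8)
            want = self._dense_oracle(attn, x[0].reshape(16, 8))
            assert np.max(np.abs(got - want)) < 1e-5

    def test_constant_tile_stays_constant(self):
        attn = WindowAttention(8, window=4, heads=2, rng=np.random.default_rng(1))
        x = np.broadcast_to(
            np.random.default_rng(2).normal(size=(1, 1, 1, 8)), (1, 4, 4, 8)
        ).astype(np.float32)
        out = attn.forward(x, train=False)
        np.testing.assert_allclose(out, np.broadcast_to(out[:, :1, :1], out.shape),
                                   atol=1e-6)

    def test_no_cross_window_leakage(self, rng):
        attn = WindowAttention(8, window=4, heads=2, rng=np.random.default_rng(5))
        x = rng.normal(size=(1, 8, 8, 8)).astype(np.float32)
        base = attn.forward(x, train=False)
        x2 = x.copy()
        x2[0, 6, 6] += 10.0  # perturb a pixel in the bottom-right window
        out = attn.forward(x2, train=False)
        np.testing.assert_array_equal(out[0, :4, :4], base[0, :4, :4])

    def test_tiles_joint_vs_separate(self, rng):
        attn = WindowAttention(8, window=4, heads=1, rng=np.random.default_rng(6))
        x = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
        joint = attn.forward(x, train=False)
        left = attn.forward(x[:, :, :4], train=False)
        right = attn.forward(x[:, :, 4:], train=False)
        np.testing.assert_allclose(joint[:, :, :4], left, atol=1e-6)
        np.testing.assert_allclose(joint[:, :, 4:], right, atol=1e-6)


class TestDepthwiseConv:
    def test_identity_kernel(self, rng):
        conv = DepthwiseConv3x3(3, np.random.default_rng(0))
        conv.W.data[...] = 0
        conv.W.data[1, 1] = 1.0
        conv.b.data[...] = 0
        x = rng.normal(size=(2, 10, 10, 3)).astype(np.float32)
        np.testing.assert_allclose(conv.forward(x, train=False), x, atol=1e-7)

    def test_impulse_response_matches_correlate_oracle(self):
        conv = DepthwiseConv3x3(1, np.random.default_rng(1))
        conv.b.data[...] = 0
        x = np.zeros((1, 7, 7, 1), dtype=np.float32)
        x[0, 3, 3, 0] = 1.0
        got = conv.forward(x, train=False)[0, :, :, 0]
        want = ndimage.correlate(
            x[0, :, :, 0], conv.W.data[:, :, 0], mode="constant"
        )
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_channels_never_mix(self, rng):
        conv = DepthwiseConv3x3(2, np.random.default_rng(2))
        x = rng.normal(size=(1, 8, 8, 2)).astype(np.float32)
        base = conv.forward(x, train=False)
        x2 = x.copy()
        x2[..., 1] = rng.normal(size=(1, 8, 8))
        out = conv.forward(x2, train=False)
        np.testing.assert_array_equal(out[..., 0], base[..., 0])


class TestInteractions:
    def test_zero_input_zero_weights_gate_half(self):
        rng0 = np.random.default_rng(0)
        ch = ChannelInteraction(8, rng0)
        ch.fc1.W.data[...] = 0; ch.fc1.b.data[...] = 0
        ch.fc2.W.data[...] = 0; ch.fc2.b.data[...] = 0
        g = ch.forward(np.zeros((2, 6, 6, 8), np.float32), train=False)
        np.testing.assert_array_equal(g, 0.5)
        sp = SpatialInteraction(8, rng0)
        sp.fc.W.data[...] = 0; sp.fc.b.data[...] = 0
        g2 = sp.forward(np.zeros((2, 6, 6, 8), np.float32), train=False)
        np.testing.assert_array_equal(g2, 0.5)

    def test_gates_in_open_unit_interval(self, rng):
        ch = ChannelInteraction(8, np.random.default_rng(1))
        sp = SpatialInteraction(8, np.random.default_rng(2))
        x = (2 * rng.normal(size=(2, 6, 6, 8))).astype(np.float32)
        for g in (ch.forward(x, train=False), sp.forward(x, train=False)):
            assert np.all((g > 0) & (g < 1))

    def test_channel_gate_invariant_to_spatial_extent(self, rng):
        ch = ChannelInteraction(4, np.random.default_rng(3))
        v = rng.normal(size=(1, 1, 1, 4)).astype(np.float32)
        small = np.broadcast_to(v, (1, 4, 4, 4)).copy()
        large = np.broadcast_to(v, (1, 8, 8, 4)).copy()
        np.testing.assert_allclose(
            ch.forward(small, train=False)[:, 0, 0],
            ch.forward(large, train=False)[:, 0, 0],
            atol=1e-7,
        )

    def test_spatial_gate_permutes_with_input(self, rng):
        sp = SpatialInteraction(4, np.random.default_rng(4))
        x = rng.normal(size=(1, 6, 6, 4)).astype(np.float32)
        g = sp.forward(x, train=False)
        perm = rng.permutation(36)
        xp = x.reshape(1, 36, 4)[:, perm].reshape(1, 6, 6, 4)
        gp = sp.forward(xp, train=False)
        np.testing.assert_allclose(gp.reshape(36), g.reshape(36)[perm], atol=1e-7)


def _block(channels=8, seed=0, **kw):
    kw.setdefault("conv_branch", True)
    kw.setdefault("attn_branch", True)
    kw.setdefault("interactions", True)
    return MixingBlock(
        channels, window=4, heads=2, ffn_ratio=4,
        reverse_interactions=False, rng=np.random.default_rng(seed), **kw
    )


class TestMixingBlock:
    def test_shape_preserved_across_widths(self, rng):
        for c, hw in ((8, 12), (16, 6)):
            blk = MixingBlock(c, 4, max(1, c // 16), 4, True, True, True, False,
                              np.random.default_rng(0))
            x = rng.normal(size=(2, hw, hw, c)).astype(np.float32)
            assert blk.forward(x, train=False).shape == x.shape

    def test_conv_only_has_no_attention_parameters(self):
        blk = _block(attn_branch=False, interactions=False)
        names = [n for n, _ in blk.named_parameters()]
        assert not any("attn" in n for n in names)
        assert any("conv" in n for n in names)

    def test_both_branches_required(self):
        with pytest.raises(ValueError):
            _block(conv_branch=False, attn_branch=False)

    def test_zeroed_gates_scale_branches_by_half(self, rng):
        """With zero-initialized gate projections both sigmoid gates are 1/2,
        so each branch output entering the fusion is exactly halved relative
        to the interaction-free block."""
        full = _block(seed=7)
        for mod in (full.ch_gate.fc1, full.ch_gate.fc2, full.sp_gate.fc):
            mod.W.data[...] = 0
            mod.b.data[...] = 0
        plain = _block(seed=8, interactions=False)
        # share branch weights
        state = dict(full.named_parameters())
        for name, p in plain.named_parameters():
            if name in state:
                p.data[...] = state[name].data
        x = rng.normal(size=(1, 8, 8, 8)).astype(np.float32)
        xn = full.norm.forward(x, train=False)
        a = full.attn.forward(xn, train=False)
        c = full.conv.forward(xn, train=False)
        gch = full.ch_gate.forward(c, train=False)
        gsp = full.sp_gate.forward(a, train=False)
        np.testing.assert_allclose(a * gch, 0.5 * a, atol=1e-7)
        np.testing.assert_allclose(c * gsp, 0.5 * c, atol=1e-7)


class TestBuildNetwork:
    def test_forward_shapes_and_simplex(self, rng):
        net = build_network(NetworkConfig(in_channels=41, base_width=8, seed=0))
        x = rng.normal(size=(1, 48, 48, 41)).astype(np.float32)
        p = net.forward(x, train=False)
        assert p.shape == (1, 48, 48, 2)
        np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-6)
        x2 = rng.normal(size=(1, 80, 80, 41)).astype(np.float32)
        assert net.forward(x2, train=False).shape == (1, 80, 80, 2)

    def test_ablation_parameter_ordering(self):
        kw = dict(in_channels=41, base_width=8, seed=0)
        conv_only = build_network(NetworkConfig(conv_branch=True, attn_branch=False, **kw))
        attn_only = build_network(NetworkConfig(conv_branch=False, attn_branch=True, **kw))
        both = build_network(NetworkConfig(interactions=False, **kw))
        full = build_network(NetworkConfig(**kw))
        assert conv_only.n_params() < both.n_params() <= full.n_params()
        assert attn_only.n_params() < both.n_params()

    def test_literal_channel_expansion_widths(self):
        cfg = NetworkConfig(in_channels=41, literal_widths=True)
        assert cfg.stage_widths() == (82, 164, 328, 656)

    def test_heads_default_rule(self):
        cfg = NetworkConfig(in_channels=41, base_width=32)
        assert cfg.stage_heads() == (2, 4, 8, 16)
        cfg8 = NetworkConfig(in_channels=41, base_width=8)
        assert cfg8.stage_heads() == (1, 1, 2, 4)

    def test_single_step_reduces_loss(self, rng):
        from cestmix.training import combined_loss

        net = build_network(NetworkConfig(in_channels=5, base_width=8, seed=1))
        x = rng.normal(size=(1, 16, 16, 5)).astype(np.float32)
        y = (rng.random((1, 16, 16)) > 0.5).astype(np.int64)
        opt = SGD(net.parameters(), lr=0.05, momentum=0.0)

        def loss_now():
            p = net.forward(x, train=False)
            return combined_loss(p, y, (1.0, 1.0))[0]

        before = loss_now()
        net.zero_grad()
        p = net.forward(x, train=True)
        _, dp = combined_loss(p, y, (1.0, 1.0))
        net.backward(dp.astype(np.float32))
        opt.step()
        assert loss_now() < before

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(depths=(2, 2))
        with pytest.raises(ValueError):
            NetworkConfig(conv_branch=False, attn_branch=False)
        net = build_network(NetworkConfig(in_channels=3, base_width=8))
        with pytest.raises(ValueError, match="divisible"):
            net.forward(np.zeros((1, 20, 20, 3), np.float32), train=False)


class TestSpectralMLP:
    def _toy(self, rng, n=400):
        # two classes of spectra with shifted Gaussian dip amplitudes
        offs = np.linspace(-5, 5, 41)
        amp = np.where(rng.random(n) > 0.5, 0.3, 0.6)
        y = (amp > 0.45).astype(int)
        X = 1.0 - amp[:, None] * np.exp(-0.5 * ((offs - 3.5) / 0.8) ** 2)
        X += rng.normal(0, 0.02, X.shape)
        return X, y

    def test_separable_toy_reaches_95pct(self, rng):
        from cestmix.models import SpectralMLPClassifier

        X, y = self._toy(rng)
        clf = SpectralMLPClassifier(max_iter=400, seed=0).fit(X[:300], y[:300])
        assert clf.mlp_.score(X[300:], y[300:]) >= 0.95

    def test_pixel_permutation_equivariance(self, rng):
        from cestmix.models import SpectralMLPClassifier, spectral_mlp_baseline

        X, y = self._toy(rng)
        clf = SpectralMLPClassifier(max_iter=200, seed=0).fit(X, y)
        img = X[:64].reshape(8, 8, 41)
        probs = spectral_mlp_baseline(img, clf)
        perm = rng.permutation(64)
        img_p = img.reshape(64, 41)[perm].reshape(8, 8, 41)
        probs_p = spectral_mlp_baseline(img_p, clf)
        np.testing.assert_allclose(
            probs_p.reshape(64, 2), probs.reshape(64, 2)[perm], atol=1e-12
        )
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-9)

    def test_wrong_spectrum_length_rejected(self, rng):
        from cestmix.models import SpectralMLPClassifier

        X, y = self._toy(rng, n=100)
        clf = SpectralMLPClassifier(max_iter=50, seed=0).fit(X, y)
        with pytest.raises(ValueError, match="length"):
            clf.predict(np.zeros((4, 17)))
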