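"""Attention blocks: multi-scale aggregation, channel attention, gate, fusion."""

import numpy as np
import pytest

from prostreg._autograd import Tensor
from prostreg.attention import (
    CrossModalAttention, CrossModalGate, DynamicChannelAttention, FuseConv,
    MultiScaleAggregation,
)


def _identity_conv_weights(channels, kernel):
    """Kernel that copies the input: center-tap identity over channels."""
    w = np.zeros((channels, channels, kernel, kernel, kernel), dtype=np.float32)
    c = kernel // 2
    for i in range(channels):
        w[i, i, c, c, c] = 1.0
    return w


class TestMultiScale:
    def test_identity_convs_give_uniform_weights(self, rng):
        msfa = MultiScaleAggregation(2, rng)
        for conv, k in zip(msfa.convs, msfa.kernels):
            conv.weight.data = _identity_conv_weights(2, k)
            conv.bias.data = np.zeros(2, dtype=np.float32)
        x = Tensor(rng.standard_normal((2, 2, 4, 4, 4)).astype(np.float32))
        weights = msfa.scale_weights(x)
        np.testing.assert_allclose(weights, 1.0 / 3.0, atol=1e-6)
        out = msfa(x)
        np.testing.assert_allclose(out.data, x.data, atol=1e-5)

    def test_scale_weights_sum_to_one(self, rng):
        msfa = MultiScaleAggregation(4, rng)
        x = Tensor(rng.standard_normal((3, 4, 6, 6, 6)).astype(np.float32))
        w = msfa.scale_weights(x)
        assert w.shape == (3, 3)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)

    def test_tiny_instance_matches_hand_computation(self, rng):
        # 1 channel, 2^3 grid, hand-set constant kernels -> brute-force oracle
        msfa = MultiScaleAggregation(1, rng)
        taps = (0.5, 0.1, -0.2)
        for conv, k, tap in zip(msfa.convs, msfa.kernels, taps):
            conv.weight.data = np.full((1, 1, k, k, k), tap, dtype=np.float32)
            conv.bias.data = np.zeros(1, dtype=np.float32)
        x = rng.standard_normal((1, 1, 2, 2, 2)).astype(np.float32)

        from scipy import ndimage
        feats, scores = [], []
        for k, tap in zip(msfa.kernels, taps):
            f = ndimage.correlate(
                x[0, 0].astype(np.float64), np.full((k, k, k), tap), mode="constant"
            )[None, None]
            feats.append(f)
            scores.append(f.mean() + f.max())
        e = np.exp(scores - np.max(scores))
        w = e / e.sum()
        expected = sum(wk * fk for wk, fk in zip(w, feats))
        np.testing.assert_allclose(msfa(Tensor(x)).data, expected, atol=1e-5)

    def test_nonfinite_rejected(self, rng):
        msfa = MultiScaleAggregation(1, rng)
        bad = np.zeros((1, 1, 4, 4, 4), dtype=np.float32)
        bad[0, 0, 0, 0, 0] = np.inf
        with pytest.raises(FloatingPointError):
            msfa(Tensor(bad))


class TestChannelAttention:
    def test_weights_in_open_interval(self, rng):
        dca = DynamicChannelAttention(4, rng)
        x = Tensor(rng.standard_normal((2, 4, 4, 4, 4)).astype(np.float32))
        w = dca.channel_weights(x).data
        assert (w > 0).all() and (w < 1).all()

    def test_zero_input_halves(self, rng):
        dca = DynamicChannelAttention(3, rng)
        dca.bias.data = np.zeros(1, dtype=np.float32)
        x = Tensor(np.zeros((1, 3, 2, 2, 2), dtype=np.float32))
        np.testing.assert_allclose(dca.channel_weights(x).data, 0.5, atol=1e-7)
        np.testing.assert_allclose(dca(x).data, 0.0)

    def test_identity_kernel_closed_form(self, rng):
        dca = DynamicChannelAttention(2, rng)
        dca.weight.data = np.array([0.0, 1.0, 0.0], dtype=np.float32)
        dca.bias.data = np.zeros(1, dtype=np.float32)
        x = rng.standard_normal((1, 2, 3, 3, 3)).astype(np.float32)
        out = dca(Tensor(x)).data
        for c in range(2):
            s = 1.0 / (1.0 + np.exp(-x[0, c].mean()))
            np.testing.assert_allclose(out[0, c], x[0, c] * s, atol=1e-6)

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError):
            DynamicChannelAttention(4, rng, kernel=2)


class TestGate:
    def test_zero_params_give_half_attention(self, rng):
        gate = CrossModalGate(4, rng)
        for p in gate.parameters():
            p.data = np.zeros_like(p.data)
        f = Tensor(rng.standard_normal((1, 4, 3, 3, 3)).astype(np.float32))
        g = Tensor(rng.standard_normal((1, 4, 3, 3, 3)).astype(np.float32))
        att, gated = gate(f, g)
        np.testing.assert_allclose(att.data, 0.5, atol=1e-7)
        np.testing.assert_allclose(gated.data, 0.5 * g.data, atol=1e-6)

    def test_attention_in_open_interval(self, rng):
        gate = CrossModalGate(6, rng)
        f = Tensor(rng.standard_normal((2, 6, 4, 4, 4)).astype(np.float32))
        g = Tensor(rng.standard_normal((2, 6, 4, 4, 4)).astype(np.float32))
        att, _ = gate(f, g)
        assert att.shape == (2, 1, 4, 4, 4)
        assert (att.data > 0).all() and (att.data < 1).all()

    def test_single_voxel_hand_computation(self, rng):
        gate = CrossModalGate(2, rng)
        gate.w1.data = np.array([[1.0], [2.0]], dtype=np.float32)
        gate.w2.data = np.array([[-1.0], [0.5]], dtype=np.float32)
        gate.w3.data = np.array([[2.0]], dtype=np.float32)
        gate.b12.data = np.array([0.25], dtype=np.float32)
        gate.b3.data = np.array([-0.5], dtype=np.float32)
        f1 = np.array([0.3, -0.2], dtype=np.float32).reshape(1, 2, 1, 1, 1)
        f2 = np.array([1.0, 0.4], dtype=np.float32).reshape(1, 2, 1, 1, 1)
        hidden = max(0.0, 1.0 * 0.3 + 2.0 * -0.2 + (-1.0 * 1.0 + 0.5 * 0.4) + 0.25)
        expected = 1.0 / (1.0 + np.exp(-(2.0 * hidden - 0.5)))
        att, gated = gate(Tensor(f1), Tensor(f2))
        np.testing.assert_allclose(att.data.ravel(), expected, atol=1e-6)
        np.testing.assert_allclose(gated.data, expected * f2, atol=1e-6)

    def test_odd_channels_rejected(self, rng):
        with pytest.raises(ValueError, match="even"):
            CrossModalGate(3, rng)

    def test_gated_output_bounded_by_input(self, rng):
        gate = CrossModalGate(4, rng)
        f = Tensor(rng.standard_normal((1, 4, 3, 3, 3)).astype(np.float32))
        g = Tensor(rng.standard_normal((1, 4, 3, 3, 3)).astype(np.float32))
        _, gated = gate(f, g)
        assert (np.abs(gated.data) <= np.abs(g.data) + 1e-7).all()


class TestCrossModalAttention:
    def test_output_shapes(self, rng):
        att = CrossModalAttention(4, rng)
        f = Tensor(rng.standard_normal((2, 4, 4, 4, 4)).astype(np.float32))
        g = Tensor(rng.standard_normal((2, 4, 4, 4, 4)).astype(np.float32))
        o1, o2 = att(f, g)
        assert o1.shape == f.shape and o2.shape == g.shape

    def test_zero_inputs_give_zero_gated(self, rng):
        att = CrossModalAttention(4, rng)
        z = Tensor(np.zeros((1, 4, 4, 4, 4), dtype=np.float32))
        o1, o2 = att(z, z)
        np.testing.assert_allclose(o1.data, 0.0, atol=1e-6)
        np.testing.assert_allclose(o2.data, 0.0, atol=1e-6)

    def test_reduces_to_plain_gate_without_msfa_dca(self, rng):
        att = CrossModalAttention(4, np.random.default_rng(3), gate_mode="f2_only",
                                  enable_msfa=False, enable_dca=False)
        f = Tensor(rng.standard_normal((1, 4, 3, 3, 3)).astype(np.float32))
        g = Tensor(rng.standard_normal((1, 4, 3, 3, 3)).astype(np.float32))
        o1, o2 = att(f, g)
        _, direct = att.gate_21(f, g)
        np.testing.assert_array_equal(o2.data, direct.data)
        np.testing.assert_array_equal(o1.data, f.data)  # ungated stream passes

    def test_batch_permutation_equivariance(self, rng):
        att = CrossModalAttention(4, rng)
        f = rng.standard_normal((3, 4, 4, 4, 4)).astype(np.float32)
        g = rng.standard_normal((3, 4, 4, 4, 4)).astype(np.float32)
        o1, o2 = att(Tensor(f), Tensor(g))
        perm = np.array([2, 0, 1])
        p1, p2 = att(Tensor(f[perm]), Tensor(g[perm]))
        np.testing.assert_allclose(p1.data, o1.data[perm], atol=1e-5)
        np.testing.assert_allclose(p2.data, o2.data[perm], atol=1e-5)

    def test_bad_gate_mode_rejected(self, rng):
        with pytest.raises(ValueError):
            CrossModalAttention(4, rng, gate_mode="both")

    def test_shape_mismatch_rejected(self, rng):
        att = CrossModalAttention(4, rng)
        with pytest.raises(ValueError):
            att(Tensor(np.zeros((1, 4, 4, 4, 4), dtype=np.float32)),
                Tensor(np.zeros((1, 4, 4, 4, 2), dtype=np.float32)))


class TestFuseConv:
    def test_identity_selection(self, rng):
        fuse = FuseConv(4, 2, rng)
        w = np.zeros((2, 4, 1, 1, 1), dtype=np.float32)
        w[0, 0, 0, 0, 0] = 1.0
        w[1, 1, 0, 0, 0] = 1.0
        fuse.conv.weight.data = w
        fuse.conv.bias.data = np.zeros(2, dtype=np.float32)
        a = Tensor(np.abs(rng.standard_normal((1, 2, 3, 3, 3))).astype(np.float32))
        b = Tensor(rng.standard_normal((1, 2, 3, 3, 3)).astype(np.float32))
        out = fuse(a, b)
        np.testing.assert_allclose(out.data, a.data, atol=1e-6)

    def test_leaky_slope_on_negative_preactivation(self, rng):
        fuse = FuseConv(2, 1, rng)
        fuse.conv.weight.data = np.array([[[[[1.0]]], [[[0.0]]]]], dtype=np.float32)
        fuse.conv.bias.data = np.zeros(1, dtype=np.float32)
        a = Tensor(np.full((1, 1, 2, 2, 2), -3.0, dtype=np.float32))
        b = Tensor(np.zeros((1, 1, 2, 2, 2), dtype=np.float32))
        np.testing.assert_allclose(fuse(a, b).data, -0.6, atol=1e-6)

    def test_scalar_toy(self, rng):
        fuse = FuseConv(2, 1, rng)
        wa, wb, bias = 0.7, -0.3, 0.1
        fuse.conv.weight.data = np.array(
            [[[[[wa]]], [[[wb]]]]], dtype=np.float32
        )
        fuse.conv.bias.data = np.array([bias], dtype=np.float32)
        a, b = 2.0, 5.0
        pre = wa * a + wb * b + bias
        expected = pre if pre > 0 else 0.2 * pre
        out = fuse(
            Tensor(np.full((1, 1, 1, 1, 1), a, dtype=np.float32)),
            Tensor(np.full((1, 1, 1, 1, 1), b, dtype=np.float32)),
        )
        np.testing.assert_allclose(out.data.item(), expected, atol=1e-6)
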