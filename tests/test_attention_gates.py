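"""CBAM and multi-scale MCBAM gating."""

import numpy as np
import pytest
from scipy.special import expit

from msa_maxnet.attention_gates import (
    CBAM, CBAMConfig, ChannelAttention, MCBAM, MCBAMChannelGate,
    MCBAMSpatialGate, SpatialAttention,
)
from msa_maxnet.nn import Tensor
from tests.conftest import zero_params

CFG8 = CBAMConfig(channels=8, reduction=4, spatial_kernel=3)


def channel_attention_oracle(f, w0, w1):
    """Loop-based shared-MLP channel gate."""
    c = f.shape[-1]
    flat = f.reshape(-1, c)
    avg, mx = flat.mean(axis=0), flat.max(axis=0)
    mlp = lambda d: np.maximum(d @ w0, 0) @ w1
    return expit(mlp(avg) + mlp(mx))


def spatial_attention_oracle(f, w, b, k):
    """Loop-based [avg;max]->conv->sigmoid spatial gate."""
    h, wd, c = f.shape
    stacked = np.stack([f.mean(axis=-1), f.max(axis=-1)], axis=-1)
    pad = k // 2
    padded = np.pad(stacked, ((pad, pad), (pad, pad), (0, 0)))
    out = np.zeros((h, wd))
    for i in range(h):
        for j in range(wd):
            out[i, j] = np.sum(padded[i:i + k, j:j + k, :] * w) + b
    return expit(out)


class TestChannelAttention:
    def test_zero_weights_give_half(self, rng):
        ca = zero_params(ChannelAttention(CFG8))
        g = ca(Tensor(rng.normal(size=(1, 4, 4, 8)).astype(np.float32))).data
        np.testing.assert_array_equal(g, 0.5)

    def test_constant_map_doubles_descriptor(self, rng):
        ca = ChannelAttention(CFG8, rng=rng)
        const = rng.normal(size=8).astype(np.float32)
        f = Tensor(np.broadcast_to(const, (1, 5, 5, 8)).copy())
        w0, w1 = ca.fc1.weight.data, ca.fc2.weight.data
        expected = expit(2 * (np.maximum(const @ w0, 0) @ w1))
        np.testing.assert_allclose(ca(f).data[0, 0, 0], expected, atol=1e-6)

    def test_matches_loop_oracle(self, rng):
        ca = ChannelAttention(CFG8, rng=rng)
        f = rng.normal(size=(4, 4, 8)).astype(np.float64)
        got = ca(Tensor(f[None].astype(np.float32))).data[0, 0, 0]
        expected = channel_attention_oracle(f, ca.fc1.weight.data, ca.fc2.weight.data)
        np.testing.assert_allclose(got, expected, atol=1e-5)


class TestSpatialAttention:
    def test_zero_weights_give_half(self, rng):
        sa = zero_params(SpatialAttention(CFG8))
        g = sa(Tensor(rng.normal(size=(1, 5, 5, 8)).astype(np.float32))).data
        np.testing.assert_array_equal(g, 0.5)

    def test_single_channel_avg_equals_max(self, rng):
        cfg = CBAMConfig(channels=4, reduction=2, spatial_kernel=3)
        sa = SpatialAttention(cfg, rng=rng)
        f = rng.normal(size=(1, 4, 4, 1)).astype(np.float32)
        # with one channel both pooled maps equal f itself
        doubled = np.concatenate([f, f], axis=-1)
        expected = sa.conv(Tensor(doubled)).sigmoid().data
        np.testing.assert_allclose(sa(Tensor(f)).data, expected, atol=1e-7)

    def test_matches_loop_oracle(self, rng):
        sa = SpatialAttention(CFG8, rng=rng)
        f = rng.normal(size=(6, 6, 8)).astype(np.float64)
        got = sa(Tensor(f[None].astype(np.float32))).data[0, :, :, 0]
        expected = spatial_attention_oracle(
            f, sa.conv.weight.data[:, :, :, 0], float(sa.conv.bias.data[0]), 3)
        np.testing.assert_allclose(got, expected, atol=1e-5)


class TestCBAM:
    def test_zero_weights_quarter_input(self, rng):
        cbam = zero_params(CBAM(CFG8))
        x = rng.normal(size=(2, 4, 4, 8)).astype(np.float32)
        np.testing.assert_array_equal(cbam(Tensor(x)).data, x / 4)

    def test_bottleneck_shape_preserved(self, rng):
        cbam = CBAM(CBAMConfig(512, 16, 7), rng=rng)
        x = Tensor(rng.normal(size=(1, 7, 7, 512)).astype(np.float32))
        assert cbam(x).shape == (1, 7, 7, 512)

    def test_equals_two_stage_composition(self, rng):
        cbam = CBAM(CFG8, rng=rng)
        f = Tensor(rng.normal(size=(1, 5, 5, 8)).astype(np.float32))
        refined = f * cbam.channel(f)
        expected = (refined * cbam.spatial(refined)).data
        np.testing.assert_allclose(cbam(f).data, expected, atol=1e-7)

    def test_maps_bounded_and_shape_kept(self, rng):
        cbam = CBAM(CFG8, rng=rng)
        f = Tensor(rng.normal(size=(1, 4, 4, 8)).astype(np.float32))
        mc = cbam.channel(f).data
        ms = cbam.spatial(f).data
        assert ((mc > 0) & (mc < 1)).all() and ((ms > 0) & (ms < 1)).all()
        assert cbam(f).shape == f.shape


class TestMCBAMChannelGate:
    def test_zero_weights_give_half(self, rng):
        gate = zero_params(MCBAMChannelGate(4))
        g = gate(Tensor(rng.normal(size=(1, 2, 2, 8)).astype(np.float32))).data
        assert g.shape == (1, 1, 1, 4)
        np.testing.assert_array_equal(g, 0.5)

    def test_output_channel_count(self, rng):
        gate = MCBAMChannelGate(64, rng=rng)
        f2 = Tensor(rng.normal(size=(1, 4, 4, 128)).astype(np.float32))
        assert gate(f2).shape == (1, 1, 1, 64)

    def test_channel_relation_enforced(self, rng):
        with pytest.raises(ValueError, match="2\\*C0"):
            MCBAMChannelGate(4, rng=rng)(
                Tensor(np.zeros((1, 2, 2, 6), dtype=np.float32)))

    def test_matches_loop_oracle(self, rng):
        gate = MCBAMChannelGate(3, rng=rng)
        f2 = rng.normal(size=(5, 5, 6)).astype(np.float64)
        got = gate(Tensor(f2[None].astype(np.float32))).data[0, 0, 0]
        w, b = gate.conv_avg.weight.data, gate.conv_avg.bias.data
        flat = f2.reshape(-1, 6)
        expected = expit((flat.mean(axis=0) @ w + b) + (flat.max(axis=0) @ w + b))
        np.testing.assert_allclose(got, expected, atol=1e-5)

    def test_separate_convolutions_flag(self, rng):
        shared = MCBAMChannelGate(4, shared=True, rng=rng)
        split = MCBAMChannelGate(4, shared=False, rng=rng)
        assert sum(p.size for p in shared.parameters()) * 2 == \
            sum(p.size for p in split.parameters())


class TestMCBAMSpatialGate:
    def test_zero_weights_give_half_in_both_modes(self, rng):
        gate = zero_params(MCBAMSpatialGate(4, kernel=3))
        f1 = Tensor(rng.normal(size=(1, 8, 8, 4)).astype(np.float32))
        np.testing.assert_array_equal(gate(f1, 4, 4).data, 0.5)  # train mode
        gate.eval()
        np.testing.assert_array_equal(gate(f1, 4, 4).data, 0.5)

    def test_full_scale_extents(self, rng):
        gate = MCBAMSpatialGate(64, kernel=7, rng=rng)
        gate.eval()
        f1 = Tensor(rng.normal(size=(1, 112, 112, 64)).astype(np.float32))
        assert gate(f1, 56, 56).shape == (1, 56, 56, 1)

    def test_extent_relation_enforced(self, rng):
        gate = MCBAMSpatialGate(4, kernel=3, rng=rng)
        with pytest.raises(ValueError, match="twice"):
            gate(Tensor(np.zeros((1, 6, 6, 4), dtype=np.float32)), 4, 4)

    def test_strided_conv_indexing_matches_enumeration(self, rng):
        gate = MCBAMSpatialGate(1, kernel=3, rng=rng)
        gate.eval()
        f1 = rng.normal(size=(4, 4, 1)).astype(np.float64)
        got = gate(Tensor(f1[None].astype(np.float32)), 2, 2).data[0, :, :, 0]
        w = gate.conv.weight.data[:, :, 0, 0]
        b = float(gate.conv.bias.data[0])
        padded = np.pad(f1[:, :, 0], 1)
        expected = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                expected[i, j] = np.sum(padded[2 * i:2 * i + 3, 2 * j:2 * j + 3] * w) + b
        np.testing.assert_allclose(got, expit(expected), atol=1e-5)


class TestMCBAM:
    def _inputs(self, rng, c0=4, h0=4):
        f0 = rng.normal(size=(1, h0, h0, c0)).astype(np.float32)
        f1 = rng.normal(size=(1, 2 * h0, 2 * h0, 2)).astype(np.float32)
        f2 = rng.normal(size=(1, h0 // 2, h0 // 2, 2 * c0)).astype(np.float32)
        return f0, f1, f2

    def test_zero_weights_quarter_f0(self, rng):
        mcbam = zero_params(MCBAM(4, 2, kernel=3))
        f0, f1, f2 = self._inputs(rng)
        np.testing.assert_array_equal(
            mcbam(Tensor(f0), Tensor(f1), Tensor(f2)).data, f0 / 4)

    def test_output_shape_is_current_stage(self, rng):
        mcbam = MCBAM(4, 2, kernel=3, rng=rng)
        f0, f1, f2 = self._inputs(rng)
        assert mcbam(Tensor(f0), Tensor(f1), Tensor(f2)).shape == f0.shape

    def test_composition_of_gate_ops(self, rng):
        mcbam = MCBAM(4, 2, kernel=3, rng=rng)
        f0, f1, f2 = map(Tensor, self._inputs(rng))
        expected = ((f0 * mcbam.channel_gate(f2))
                    * mcbam.spatial_gate(f1, 4, 4)).data
        np.testing.assert_allclose(mcbam(f0, f1, f2).data, expected, atol=1e-7)

    def test_output_bounded_by_f0(self, rng):
        mcbam = MCBAM(4, 2, kernel=3, rng=rng)
        f0, f1, f2 = self._inputs(rng)
        out = mcbam(Tensor(f0), Tensor(f1), Tensor(f2)).data
        assert (np.abs(out) <= np.abs(f0) + 1e-7).all()

    def test_dimension_relations_enforced(self, rng):
        mcbam = MCBAM(4, 2, kernel=3, rng=rng)
        f0, f1, f2 = self._inputs(rng)
        bad_f2 = np.zeros((1, 4, 4, 8), dtype=np.float32)  # wrong resolution
        with pytest.raises(ValueError, match="half"):
            mcbam(Tensor(f0), Tensor(f1), Tensor(bad_f2))
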