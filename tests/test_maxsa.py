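"""Block/grid partitioning, relative attention and the Max-SA layers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msa_maxnet.maxsa import (
    AttentionConfig, BlockAttentionLayer, FeedForward, GridAttentionLayer,
    MaxViTBlock, RelativeBiasTable, block_partition, grid_partition,
    relative_attention, relative_index_map, unblock, ungrid,
)
from msa_maxnet.nn import Tensor
from tests.conftest import zero_params


def seq_map(h, w, c=1):
    """(h, w, c) map whose channel-0 values are 0..h*w-1 row-major."""
    x = np.arange(h * w, dtype=np.float64).reshape(h, w, 1)
    return np.repeat(x, c, axis=-1)


class TestPartitioning:
    def test_block_shape_arithmetic(self):
        ws = block_partition(np.zeros((8, 8, 5)), 4)
        assert ws.windows.shape == (1, 4, 16, 5)

    def test_single_window_is_flattened_input(self):
        x = np.random.default_rng(0).normal(size=(3, 3, 2))
        ws = block_partition(x, 3)
        np.testing.assert_array_equal(ws.windows[0, 0], x.reshape(9, 2))

    def test_block_tile_enumeration(self):
        ws = block_partition(seq_map(4, 4), 2)
        got = ws.windows[0, :, :, 0]
        np.testing.assert_array_equal(
            got, [[0, 1, 4, 5], [2, 3, 6, 7], [8, 9, 12, 13], [10, 11, 14, 15]])

    def test_grid_coset_enumeration(self):
        ws = grid_partition(seq_map(4, 4), 2)
        got = ws.windows[0, :, :, 0]
        # group 0 = inner offset (0,0): stride-2 lattice starting at the origin
        np.testing.assert_array_equal(got[0], [0, 2, 8, 10])
        np.testing.assert_array_equal(
            got, [[0, 2, 8, 10], [1, 3, 9, 11], [4, 6, 12, 14], [5, 7, 13, 15]])

    def test_grid_group_count(self):
        ws = grid_partition(np.zeros((8, 8, 3)), 2)
        assert ws.windows.shape == (1, 16, 4, 3)

    def test_grid_single_group_is_whole_map(self):
        x = np.random.default_rng(1).normal(size=(2, 2, 3))
        ws = grid_partition(x, 2)
        assert ws.windows.shape == (1, 1, 4, 3)
        np.testing.assert_array_equal(ws.windows[0, 0], x.reshape(4, 3))

    @pytest.mark.parametrize("fn", [block_partition, grid_partition])
    def test_non_divisible_extent_rejected(self, fn):
        with pytest.raises(ValueError, match="not divisible"):
            fn(np.zeros((6, 8, 1)), 4)

    @given(st.integers(1, 4), st.integers(1, 4), st.integers(1, 4),
           st.integers(1, 3), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_round_trips_are_exact(self, size, th, tw, c, seed):
        h, w = size * th, size * tw
        x = np.random.default_rng(seed).normal(size=(h, w, c))
        np.testing.assert_array_equal(unblock(block_partition(x, size)), x)
        np.testing.assert_array_equal(ungrid(grid_partition(x, size)), x)

    def test_round_trip_batched_tensor(self):
        x = Tensor(np.random.default_rng(2).normal(size=(2, 8, 8, 3)))
        np.testing.assert_array_equal(unblock(block_partition(x, 4)).data, x.data)
        np.testing.assert_array_equal(ungrid(grid_partition(x, 2)).data, x.data)

    def test_inconsistent_window_set_rejected(self):
        ws = block_partition(np.zeros((8, 8, 3)), 4)
        ws.origin_shape = (4, 4, 3)
        with pytest.raises(ValueError, match="inconsistent"):
            unblock(ws)


class TestRelativeBias:
    def test_trivial_window(self):
        t = RelativeBiasTable(1, num_heads=2)
        t.table.data[:] = [[3.5], [-1.0]]
        np.testing.assert_array_equal(t.matrix().data, [[[3.5]], [[-1.0]]])

    def test_window2_structure(self):
        idx = relative_index_map(2)
        assert idx.shape == (4, 4)
        assert len(np.unique(idx)) == 9  # all nine 2D offsets occur
        assert len(set(np.diag(idx))) == 1  # zero offset everywhere on diagonal
        # token pairs with equal offsets share a slot: (0,1) and (2,3) are both
        # "one column left" within the 2x2 window
        assert idx[0, 1] == idx[2, 3]
        assert idx[1, 0] == idx[3, 2]

    def test_bias_depends_only_on_offset(self):
        t = RelativeBiasTable(3, num_heads=1)
        t.table.data[:] = np.arange(25.0)
        m = t.matrix().data[0]
        coords = [(i, j) for i in range(3) for j in range(3)]
        for a, (r1, c1) in enumerate(coords):
            for b, (r2, c2) in enumerate(coords):
                for a2, (r3, c3) in enumerate(coords):
                    for b2, (r4, c4) in enumerate(coords):
                        if (r1 - r2, c1 - c2) == (r3 - r4, c3 - c4):
                            assert m[a, b] == m[a2, b2]


class TestRelativeAttention:
    def test_zero_query_and_bias_average_values(self, rng):
        n, d = 6, 8
        q = np.zeros((n, d))
        k = rng.normal(size=(n, d))
        v = rng.normal(size=(n, d))
        out = relative_attention(q, k, v, None, head_dim=4).data
        np.testing.assert_allclose(out, np.tile(v.mean(axis=0), (n, 1)), atol=1e-6)

    def test_single_token_returns_value(self, rng):
        q, k, v = (rng.normal(size=(1, 4)) for _ in range(3))
        np.testing.assert_allclose(
            relative_attention(q, k, v, None, head_dim=4).data, v, atol=1e-7)

    def test_nan_rejected(self, rng):
        q = rng.normal(size=(2, 4))
        q[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            relative_attention(q, q, q, None, head_dim=4)

    @staticmethod
    def oracle(q, k, v, bias, head_dim):
        """Independent double-loop softmax attention."""
        n, d = q.shape
        heads = d // head_dim
        out = np.zeros_like(v)
        for h in range(heads):
            sl = slice(h * head_dim, (h + 1) * head_dim)
            for i in range(n):
                logits = np.array([
                    q[i, sl] @ k[j, sl] / np.sqrt(head_dim)
                    + (bias[h, i, j] if bias is not None else 0.0)
                    for j in range(n)])
                w = np.exp(logits - logits.max())
                w /= w.sum()
                out[i, sl] = sum(w[j] * v[j, sl] for j in range(n))
        return out

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 17))
            heads = int(rng.choice([1, 2, 4]))
            hd = int(rng.choice([2, 4]))
            d = heads * hd
            q, k, v = (rng.normal(size=(n, d)) for _ in range(3))
            bias = rng.normal(size=(heads, n, n))
            got = relative_attention(q, k, v, bias, head_dim=hd).data
            np.testing.assert_allclose(got, self.oracle(q, k, v, bias, hd), atol=1e-5)

    def test_output_within_value_hull(self, rng):
        n, hd, heads = 9, 4, 2
        q, k, v = (rng.normal(size=(n, heads * hd)) for _ in range(3))
        out = relative_attention(q, k, v, rng.normal(size=(heads, n, n)), hd).data
        for h in range(heads):
            sl = slice(h * hd, (h + 1) * hd)
            assert (out[:, sl] <= v[:, sl].max(axis=0) + 1e-6).all()
            assert (out[:, sl] >= v[:, sl].min(axis=0) - 1e-6).all()


class TestFeedForward:
    def test_zero_weights_give_zero(self, zeroed):
        ffn = zeroed(FeedForward(6, 2.0))
        x = Tensor(np.random.default_rng(0).normal(size=(3, 6)))
        np.testing.assert_array_equal(ffn(x).data, 0.0)

    def test_position_wise_permutation_equivariance(self, rng):
        ffn = FeedForward(6, 4.0, rng=rng)
        x = rng.normal(size=(5, 6)).astype(np.float32)
        perm = rng.permutation(5)
        np.testing.assert_allclose(ffn(Tensor(x[perm])).data,
                                   ffn(Tensor(x)).data[perm], atol=1e-6)

    def test_single_token_closed_form(self):
        from scipy.special import erf
        ffn = FeedForward(2, 1.0)
        w1 = np.array([[1.0, -0.5], [0.25, 2.0]])
        b1 = np.array([0.1, -0.2])
        w2 = np.array([[0.3, 1.0], [-1.5, 0.5]])
        b2 = np.array([0.0, 0.7])
        ffn.net[0].weight.data[:] = w1
        ffn.net[0].bias.data[:] = b1
        ffn.net[2].weight.data[:] = w2
        ffn.net[2].bias.data[:] = b2
        x = np.array([[0.4, -1.2]])
        h = x @ w1 + b1
        h = h * 0.5 * (1 + erf(h / np.sqrt(2)))
        expected = h @ w2 + b2
        np.testing.assert_allclose(ffn(Tensor(x)).data, expected, atol=1e-6)


class TestAttentionLayers:
    CFG = AttentionConfig(dim=8, head_dim=4, window_p=2, grid_g=2, mlp_ratio=2.0)

    @pytest.mark.parametrize("layer_cls", [BlockAttentionLayer, GridAttentionLayer])
    def test_zeroed_residual_branches_identity(self, layer_cls, rng):
        layer = layer_cls(self.CFG, rng=rng)
        # zero only the branch exits: attention output projection and MLP W2
        for lin in (layer.proj, layer.mlp.net[2]):
            lin.weight.data[:] = 0
            lin.bias.data[:] = 0
        x = rng.normal(size=(4, 4, 8)).astype(np.float32)
        np.testing.assert_array_equal(layer(Tensor(x)).data, x)

    def test_shape_preserved_at_stage_resolution(self, rng):
        cfg = AttentionConfig(dim=64, head_dim=32, window_p=7, grid_g=7)
        x = Tensor(rng.normal(size=(1, 28, 28, 64)).astype(np.float32))
        assert BlockAttentionLayer(cfg, rng=rng)(x).shape == (1, 28, 28, 64)
        assert GridAttentionLayer(cfg, rng=rng)(x).shape == (1, 28, 28, 64)

    def test_layer_equals_composition_of_primitives(self, rng):
        layer = BlockAttentionLayer(self.CFG, rng=rng)
        trunc = np.random.default_rng(5)
        for p in layer.parameters():
            p.data[:] = trunc.normal(0, 0.5, size=p.shape).astype(np.float32)
        x = Tensor(rng.normal(size=(4, 4, 8)).astype(np.float32))
        got = layer(x).data

        d = 8
        ws = block_partition(layer.norm1(x), 2)
        qkv = layer.qkv(ws.windows)
        q, k, v = (qkv.narrow(-1, i * d, d) for i in range(3))
        att = relative_attention(q, k, v, layer.bias_table.matrix(), 4)
        from msa_maxnet.maxsa import WindowSet
        merged = unblock(WindowSet(layer.proj(att), ws.origin_shape, "block", 2,
                                   ws.batched))
        y = x + merged
        expected = (y + layer.mlp(layer.norm2(y))).data
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_maxvit_block_is_sequential_composition(self, rng):
        cfg = self.CFG
        blk = MaxViTBlock(cfg, rng=rng)
        x = Tensor(rng.normal(size=(2, 4, 4, 8)).astype(np.float32))
        np.testing.assert_array_equal(
            blk(x).data, blk.grid_attn(blk.block_attn(x)).data)

    def test_zeroed_maxvit_block_identity(self, rng):
        blk = MaxViTBlock(self.CFG, rng=rng)
        for layer in (blk.block_attn, blk.grid_attn):
            for lin in (layer.proj, layer.mlp.net[2]):
                lin.weight.data[:] = 0
                lin.bias.data[:] = 0
        x = rng.normal(size=(4, 4, 8)).astype(np.float32)
        np.testing.assert_array_equal(blk(Tensor(x)).data, x)

    def test_single_group_at_bottleneck_resolution(self, rng):
        cfg = AttentionConfig(dim=32, head_dim=32, window_p=7, grid_g=7)
        blk = MaxViTBlock(cfg, rng=rng)
        x = Tensor(rng.normal(size=(1, 7, 7, 32)).astype(np.float32))
        assert blk(x).shape == (1, 7, 7, 32)
        assert blk.block_attn.last_group_size == 49
        assert blk.grid_attn.last_group_size == 49

    def test_attention_group_size_independent_of_extent(self, rng):
        layer = BlockAttentionLayer(self.CFG, rng=rng)
        for extent in (4, 8, 12):
            layer(Tensor(rng.normal(size=(1, extent, extent, 8)).astype(np.float32)))
            assert layer.last_group_size == 4  # always P*P tokens per group
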