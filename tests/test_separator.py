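"""Segmentation/overlap-add inversion, the tiny-transformer block, and the
dual-path composition, checked against literal brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from birdsep.autodiff import Tensor, no_grad
from birdsep.config import ModelConfig
from birdsep.model import SeparationModel
from birdsep.separator import (
    ChunkTensor,
    TinyTransformerBlock,
    dual_path,
    inter_pass,
    intra_pass,
    overlap_add,
    segment,
    segment_plan,
    tiny_transformer_forward,
)


class TestSegmentation:
    @pytest.mark.parametrize(
        "L,K,expected_S,expected_tail",
        [(120, 120, 3, 0),   # padded to 240 = 60 + 120 + 0 + 60
         (100, 120, 3, 20),  # tail pad 20 aligns to hop 60
         (60, 120, 2, 0)],   # padded to 180
    )
    def test_chunk_counts(self, L, K, expected_S, expected_tail):
        P, pad_front, pad_tail, S = segment_plan(L, K)
        assert (P, pad_front) == (K // 2, K // 2)
        assert pad_tail == expected_tail
        assert S == expected_S

    def test_odd_K_rejected(self):
        with pytest.raises(ValueError, match="even"):
            segment_plan(100, 119)

    def test_every_frame_covered_twice(self, rng):
        # ones in -> after overlap-add's /2, ones out means double coverage
        f = np.ones((3, 250))
        out = overlap_add(segment(f, 120))
        np.testing.assert_allclose(out, 1.0, atol=1e-15)

    @pytest.mark.parametrize("L", [1, 59, 60, 61, 120, 7999])
    def test_exact_inversion(self, L, rng):
        f = rng.standard_normal((4, L))
        out = overlap_add(segment(f, 120))
        assert np.max(np.abs(out - f)) <= 1e-12

    def test_impulse_round_trip(self):
        f = np.zeros((1, 200))
        f[0, 137] = 3.25
        out = overlap_add(segment(f, 120))
        assert out[0, 137] == pytest.approx(3.25, abs=1e-15)
        assert np.sum(out != 0) == 1

    @given(L=st.integers(1, 500), half_K=st.integers(2, 40))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_inversion_property(self, L, half_K):
        rng = np.random.default_rng(L * 1000 + half_K)
        f = rng.standard_normal((2, L))
        out = overlap_add(segment(f, 2 * half_K))
        assert np.max(np.abs(out - f)) <= 1e-12

    def test_inconsistent_bookkeeping_rejected(self):
        with pytest.raises(ValueError, match="bookkeeping"):
            ChunkTensor(np.zeros((2, 120, 3)), pad_front=10, pad_tail=0,
                        original_len=120)


def _block(d=2, h=1, seed=0, **cfg_kw):
    kw = dict(sep_dim=d, n_heads=h, n_filters=16, chunk_len=50, n_blocks=1)
    kw.update(cfg_kw)
    cfg = ModelConfig(**kw)
    rng = np.random.default_rng(seed)
    return TinyTransformerBlock(cfg, rng=rng, dtype=np.float64)


class TestTinyTransformerBlock:
    @pytest.mark.parametrize("M", [120, 60, 17])
    def test_shape_preserved(self, M, rng):
        blk = _block(d=8, h=2)
        X = rng.standard_normal((8, M))
        assert tiny_transformer_forward(X, blk).shape == (8, M)

    def test_zero_input_zero_output(self):
        blk = _block(d=8, h=2)
        out = tiny_transformer_forward(np.zeros((8, 40)), blk)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_too_short_rejected(self, rng):
        blk = _block(d=4, h=1)
        with pytest.raises(ValueError, match="shorter"):
            tiny_transformer_forward(rng.standard_normal((4, 3)), blk)

    def test_attention_matches_triple_loop(self, rng):
        # literal softmax-attention computation on a d=2, h=1, M=6 toy
        d, M = 2, 6
        blk = _block(d=d, h=1, seed=4)
        X = rng.standard_normal((d, M))
        # reproduce the front conv to obtain the attention input Z
        from birdsep.separator import _front_padding

        front, tail, Mp = _front_padding(M, blk.kernel, blk.stride)
        with no_grad():
            z = blk.front(Tensor(X[None]).pad1d(front, tail)).data[0]  # (d, M')
        q = z.T @ blk.w_q.data
        k = z.T @ blk.w_k.data
        v = z.T @ blk.w_v.data
        attn_oracle = np.zeros((Mp, Mp))
        out_oracle = np.zeros((Mp, d))
        for i in range(Mp):
            logits = np.array([q[i] @ k[j] / math.sqrt(d) for j in range(Mp)])
            e = np.exp(logits - logits.max())
            attn_oracle[i] = e / e.sum()
            for j in range(Mp):
                out_oracle[i] += attn_oracle[i, j] * v[j]
        out_oracle = out_oracle @ blk.w_o.data
        attn = blk.attention_weights(X)[0]
        np.testing.assert_allclose(attn, attn_oracle, atol=1e-10)
        with no_grad():
            mh = blk._attention(Tensor(z[None])).data[0]
        np.testing.assert_allclose(mh, out_oracle.T, atol=1e-10)

    def test_attention_rows_sum_to_one(self, rng):
        blk = _block(d=8, h=4, seed=1)
        attn = blk.attention_weights(rng.standard_normal((8, 37)))
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-12)


class TestDualPathPasses:
    def _chunks(self, rng, d=6, L=100, K=20):
        return segment(rng.standard_normal((d, L)), K)

    def test_intra_commutes_with_chunk_permutation(self, rng):
        blk = _block(d=6, h=2, seed=2)
        D = self._chunks(rng)
        perm = rng.permutation(D.values.shape[2])
        a = intra_pass(D, blk).values[:, :, perm]
        D2 = ChunkTensor(np.ascontiguousarray(D.values[:, :, perm]),
                         D.pad_front, D.pad_tail, D.original_len)
        b = intra_pass(D2, blk).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_intra_equals_per_chunk_forward(self, rng):
        blk = _block(d=6, h=2, seed=3)
        D = self._chunks(rng)
        out = intra_pass(D, blk)
        for s in range(D.values.shape[2]):
            expected = tiny_transformer_forward(D.values[:, :, s], blk)
            np.testing.assert_allclose(out.values[:, :, s], expected, atol=1e-12)

    def test_inter_equals_transposed_intra(self, rng):
        # the inter pass is the intra pass conjugated by the K<->S swap
        blk = _block(d=6, h=2, seed=5)
        D = self._chunks(rng)
        out = inter_pass(D, blk).values
        expected = np.empty_like(out)
        for j in range(D.values.shape[1]):
            expected[:, j, :] = tiny_transformer_forward(D.values[:, j, :], blk)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_dual_path_b0_identity(self, rng):
        D = self._chunks(rng)
        out = dual_path(D, [])
        np.testing.assert_array_equal(out.values, D.values)

    def test_dual_path_b1_composition(self, rng):
        intra, inter = _block(d=6, h=2, seed=6), _block(d=6, h=2, seed=7)
        D = self._chunks(rng)
        out = dual_path(D, [intra, inter])
        expected = inter_pass(intra_pass(D, intra), inter)
        np.testing.assert_allclose(out.values, expected.values, atol=1e-12)

    def test_odd_block_count_rejected(self, rng):
        with pytest.raises(ValueError, match="even"):
            dual_path(self._chunks(rng), [_block(d=6, h=2)])

    def test_output_finite_through_deep_stack(self, rng):
        cfg = ModelConfig(sep_dim=16, n_heads=4, n_filters=32, chunk_len=20,
                          n_blocks=6)
        blocks = [
            TinyTransformerBlock(cfg, rng=np.random.default_rng(i),
                                 dtype=np.float64)
            for i in range(12)
        ]
        D = segment(rng.standard_normal((16, 100)), 20)
        out = dual_path(D, blocks)
        assert np.all(np.isfinite(out.values))


class TestSeparateEndToEnd:
    def test_output_contract(self, tiny_model, rng):
        x = rng.standard_normal(2000)
        outs = tiny_model.separate(x)
        assert len(outs) == 2
        assert all(o.shape == (2000,) for o in outs)

    def test_zero_input_zero_output(self, tiny_cfg):
        model = SeparationModel(tiny_cfg, seed=0)  # fresh weights, zero biases
        outs = model.separate(np.zeros(1000))
        for o in outs:
            np.testing.assert_allclose(o, 0.0, atol=1e-12)

    def test_deterministic(self, tiny_model, rng):
        x = rng.standard_normal(1500)
        a = tiny_model.separate(x)
        b = tiny_model.separate(x)
        for wa, wb in zip(a, b):
            np.testing.assert_array_equal(wa, wb)

    def test_mask_nonnegativity(self, tiny_model, rng):
        x = rng.standard_normal(1200).astype(np.float32)
        with no_grad():
            w = tiny_model.encoder(Tensor(x[None, None]))
            masks = tiny_model.separator(w)
        for m in masks:
            assert m.data.min() >= 0


class TestMaskPipelineOracles:
    def test_output_projection_equals_per_position_matmul(self, tiny_cfg, rng):
        # the 1x1 projection to C*d channels is a per-position matrix map
        from birdsep.separator import DualPathSeparator

        sep = DualPathSeparator(tiny_cfg, rng=np.random.default_rng(0),
                                dtype=np.float64)
        d = tiny_cfg.sep_dim
        flat = rng.standard_normal((1, d, 6))
        with no_grad():
            out = sep.out_proj(Tensor(flat)).data[0]
        W = sep.out_proj.weight.data[:, :, 0]
        b = sep.out_proj.bias.data
        expected = W @ flat[0] + b[:, None]
        np.testing.assert_allclose(out, expected, atol=1e-12)
        assert out.shape[0] == tiny_cfg.n_sources * d

    def test_mask_head_zero_in_zero_out(self, tiny_cfg, rng):
        # all-zero latent feature must produce all-zero masks at init
        from birdsep.separator import DualPathSeparator

        sep = DualPathSeparator(tiny_cfg, rng=np.random.default_rng(1),
                                dtype=np.float64)
        with no_grad():
            masks = sep(Tensor(np.zeros((1, tiny_cfg.n_filters, 90))))
        for m in masks:
            np.testing.assert_allclose(m.data, 0.0, atol=1e-12)
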