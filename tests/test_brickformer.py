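"""Dual attention: oracles for coarse/fine attention, top-k selection,
the vanilla-equivalence limit, and complexity accounting."""

import numpy as np
import pytest

from x2p.brickformer import (
    SCEUnit,
    VertebralEmbeddings,
    coarse_attention,
    complexity_estimate,
    fine_attention,
    select_topk,
)
from x2p.nn import Tensor
from x2p.nn import functional as F


def brute_force_attention(q, k, scale=None):
    if scale is None:
        scale = 1.0 / np.sqrt(q.shape[-1])
    logits = np.array([[float(qi @ kj) * scale for kj in k] for qi in q])
    out = np.empty_like(logits)
    for i, row in enumerate(logits):
        e = np.exp(row - row.max())
        out[i] = e / e.sum()
    return out


class TestCoarseAttention:
    def test_rows_sum_to_one(self, rng):
        attn = coarse_attention(rng.standard_normal((12, 8)), rng.standard_normal((16, 8)))
        np.testing.assert_allclose(attn.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_identical_keys_uniform_rows(self, rng):
        fm = np.tile(rng.standard_normal(8), (16, 1))
        attn = coarse_attention(rng.standard_normal((5, 8)), fm)
        np.testing.assert_allclose(attn.data, 1.0 / 16, atol=1e-9)

    def test_matches_brute_force_oracle(self, rng):
        e = rng.standard_normal((6, 4))
        fm = rng.standard_normal((16, 4))  # 4x4 pooled grid
        wq = rng.standard_normal((4, 4))
        wk = rng.standard_normal((4, 4))
        attn = coarse_attention(e, fm, wq, wk)
        ref = brute_force_attention(e @ wq, fm @ wk)
        np.testing.assert_allclose(attn.data, ref, atol=1e-10)


class TestSelectTopk:
    def test_block_structure(self, rng):
        attn = rng.random((10, 16))  # pooled 4x4, alpha=2 -> image 8x8
        sel = select_topk(attn, k=2, alpha=2, w=8, h=8)
        assert len(sel.coarse_indices) == 2
        assert len(sel.fine_indices) == 2 * 4
        assert len(set(sel.fine_indices.tolist())) == 8
        # fine indices tile each coarse cell's 2x2 block exactly
        for ci in sel.coarse_indices:
            cy, cx = divmod(int(ci), 4)
            block = {
                (2 * cy + dy) * 8 + (2 * cx + dx) for dy in (0, 1) for dx in (0, 1)
            }
            assert block <= set(sel.fine_indices.tolist())

    def test_k_clamped_to_full_image(self, rng):
        attn = rng.random((3, 16))
        sel = select_topk(attn, k=99, alpha=2, w=8, h=8)
        assert sorted(sel.fine_indices.tolist()) == list(range(64))

    def test_matches_brute_force_sort(self, rng):
        for _ in range(1000):
            q = int(rng.integers(1, 6))
            pw = int(rng.integers(1, 5))
            ph = int(rng.integers(1, 5))
            alpha = int(rng.integers(1, 4))
            k = int(rng.integers(1, pw * ph + 2))
            attn = rng.random((q, pw * ph))
            sel = select_topk(attn, k=k, alpha=alpha, w=pw * alpha, h=ph * alpha)
            scores = attn.max(axis=0)
            order = sorted(range(pw * ph), key=lambda i: (-scores[i], i))
            expected = sorted(order[: min(k, pw * ph)])
            assert sel.coarse_indices.tolist() == expected
            expected_fine = set()
            for ci in expected:
                cy, cx = divmod(ci, pw)
                for dy in range(alpha):
                    for dx in range(alpha):
                        expected_fine.add((cy * alpha + dy) * pw * alpha + cx * alpha + dx)
            assert set(sel.fine_indices.tolist()) == expected_fine
            assert len(sel.fine_indices) == len(expected_fine)

    def test_tie_break_smaller_index(self):
        attn = np.full((2, 9), 0.5)
        sel = select_topk(attn, k=3, alpha=1, w=3, h=3)
        assert sel.coarse_indices.tolist() == [0, 1, 2]

    def test_mean_reduction(self, rng):
        attn = rng.random((4, 9))
        sel = select_topk(attn, k=2, alpha=1, w=3, h=3, reduction="mean")
        scores = attn.mean(axis=0)
        expected = sorted(sorted(range(9), key=lambda i: (-scores[i], i))[:2])
        assert sel.coarse_indices.tolist() == expected


class TestFineAttention:
    def test_rows_sum_to_one(self, rng):
        attn2, _ = fine_attention(rng.standard_normal((8, 6)), rng.standard_normal((10, 6)))
        np.testing.assert_allclose(attn2.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_single_feature_collapses_to_value(self, rng):
        fs = rng.standard_normal((1, 6))
        wv = rng.standard_normal((6, 6))
        _, out = fine_attention(rng.standard_normal((5, 6)), fs, wv=wv)
        np.testing.assert_allclose(out.data, np.tile(fs @ wv, (5, 1)), atol=1e-10)

    def test_empty_selection_rejected(self, rng):
        with pytest.raises(ValueError, match="invalid selection"):
            fine_attention(rng.standard_normal((5, 6)), np.zeros((0, 6)))

    def test_alpha1_full_k_equals_vanilla(self, rng):
        """Coarse select-all + fine attention == vanilla attention over fm."""
        for seed in range(50):
            r = np.random.default_rng(seed)
            d, h, w = 6, 4, 4
            fm = r.standard_normal((h * w, d))
            e = r.standard_normal((8, d))
            wq, wk, wv = (r.standard_normal((d, d)) for _ in range(3))
            attn1 = coarse_attention(e, fm, wq, wk)  # alpha=1 pooled == fm
            sel = select_topk(attn1, k=h * w, alpha=1, w=w, h=h)
            fs = fm[sel.fine_indices]
            attn2, out = fine_attention(e, fs, wq, wk, wv)
            ref = brute_force_attention(e @ wq, fm @ wk) @ (fm @ wv)
            np.testing.assert_allclose(out.data, ref, atol=1e-5)


class TestComplexity:
    def test_limit_case_equality(self):
        est = complexity_estimate(16, 16, 8, 3, s=4, alpha=1, k=16 * 16, layers=4)
        assert est["brickformer_ops"] == est["vanilla_ops"]

    def test_full_scale_preset_reduces_ops(self):
        est = complexity_estimate(512, 512, 64, 10, s=16, alpha=32, k=8, layers=4)
        assert est["brickformer_ops"] < est["vanilla_ops"]
        # ratio from the two formulas directly
        m = 16 * 16 * 10
        vanilla = 4 * 512 * 512 * m * 64
        dual = 2 * ((512 * 512 / 32**2) * m * 64 + 8 * 32**2 * m * 64)
        assert est["vanilla_ops"] == vanilla
        assert est["brickformer_ops"] == dual

    def test_monotone_in_k(self):
        ops = [
            complexity_estimate(64, 64, 8, 4, s=8, alpha=8, k=k, layers=4)["brickformer_ops"]
            for k in (1, 2, 4, 8)
        ]
        assert all(b > a for a, b in zip(ops, ops[1:]))


class TestSCEUnit:
    @pytest.fixture
    def unit(self, rng):
        return SCEUnit(
            n_slots=3, d=8, embed_size=8, alpha=8, topk=2, heads=2, layers=4, rng=rng
        )

    def test_output_shapes_and_ranges(self, unit, rng):
        fm = Tensor(rng.standard_normal((8, 64, 64)).astype(np.float32))
        e_ctx, heatmaps, selections = unit(fm)
        assert e_ctx.shape == (3, 8, 8, 8)
        assert heatmaps.shape == (3, 8, 8)
        assert np.all(heatmaps.data > 0) and np.all(heatmaps.data < 1)
        assert len(selections) == 2  # 4 layers -> 2 dual blocks

    def test_alpha_must_divide(self, rng):
        unit = SCEUnit(n_slots=2, d=8, embed_size=4, alpha=7, topk=2, heads=2, rng=rng)
        with pytest.raises(ValueError, match="config error"):
            unit(Tensor(np.zeros((8, 64, 64), dtype=np.float32)))

    def test_gradients_reach_embeddings(self, unit, rng):
        fm = Tensor(rng.standard_normal((8, 64, 64)).astype(np.float32), requires_grad=True)
        e_ctx, heatmaps, _ = unit(fm)
        heatmaps.sum().backward()
        grad = unit.embeddings.e.grad
        assert grad is not None and np.any(grad != 0)
        assert fm.grad is not None and np.any(fm.grad != 0)

    def test_zero_weight_head_gives_half(self, unit, rng):
        unit.heat_head.weight.data[:] = 0
        unit.heat_head.bias.data[:] = 0
        fm = Tensor(rng.standard_normal((8, 64, 64)).astype(np.float32))
        _, heatmaps, _ = unit(fm)
        np.testing.assert_allclose(heatmaps.data, 0.5, atol=1e-7)


def test_embeddings_token_layout(rng):
    emb = VertebralEmbeddings(n_slots=2, d=3, size=4, rng=rng)
    tokens = emb.tokens()
    assert tokens.shape == (2 * 16, 3)
    # token (n, y, x) order: row-major per embedding
    np.testing.assert_allclose(tokens.data[0], emb.e.data[0, :, 0, 0])
    np.testing.assert_allclose(tokens.data[5], emb.e.data[0, :, 1, 1])
    np.testing.assert_allclose(tokens.data[16], emb.e.data[1, :, 0, 0])
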