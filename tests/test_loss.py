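"""Contrastive loss values against closed forms and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clib.loss import (LossConfig, block_to_interleaved, clib_ablation_loss,
                       clib_loss, clib_loss_interleaved, cosine_similarity,
                       drop_background, interleaved_to_block, loss_and_grad,
                       simclr_loss)
from clib.model import EmbeddingBatch


def cos(u, v):
    return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))


def oracle_loss(z, anchors_positives, denom_sets, tau):
    """Naive per-anchor double loop, the independent reference."""
    losses = []
    for i, j in anchors_positives:
        num = np.exp(cos(z[i], z[j]) / tau)
        den = sum(np.exp(cos(z[i], z[k]) / tau) for k in denom_sets[i])
        losses.append(-np.log(num / den))
    return float(np.mean(losses)), np.array(losses)


def oracle_simclr(z, n, tau):
    pairs = [(i, i + n) for i in range(n)] + [(i + n, i) for i in range(n)]
    denom = {i: [k for k in range(2 * n) if k != i] for i in range(2 * n)}
    return oracle_loss(z, pairs, denom, tau)


def oracle_three_view(z, n, tau):
    """Anchors are the first 2N slots; denominator = all 3N samples but self."""
    pairs = [(i, i + n) for i in range(n)] + [(i + n, i) for i in range(n)]
    denom = {i: [k for k in range(3 * n) if k != i] for i in range(2 * n)}
    return oracle_loss(z, pairs, denom, tau)


def emb(z, layout, n):
    return EmbeddingBatch(vectors=z, layout=layout,
                          positive_pairs=[(i, i + n) for i in range(n)],
                          n_sources=n)


class TestCosineSimilarity:
    def test_orthogonal(self):
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_self(self):
        assert cosine_similarity([2, 3, 4], [2, 3, 4]) == pytest.approx(1.0)

    def test_closed_form(self):
        assert cosine_similarity([1, 1], [1, 0]) == pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 0])

    def test_scale_invariant_symmetric(self):
        u, v = np.array([1.0, 2.0, -1.0]), np.array([0.5, -1.0, 2.0])
        assert cosine_similarity(u, v) == pytest.approx(cosine_similarity(3 * u, v))
        assert cosine_similarity(u, v) == pytest.approx(cosine_similarity(v, u))


class TestClosedForms:
    def test_simclr_single_pair_identical(self):
        z = np.ones((2, 4))
        assert simclr_loss(emb(z, "two_view", 1)).total == pytest.approx(0.0)

    def test_simclr_two_pairs_all_identical(self):
        z = np.ones((4, 8))
        v = simclr_loss(emb(z, "two_view", 2), LossConfig(0.07, "simclr"))
        assert v.total == pytest.approx(np.log(3), abs=1e-12)
        assert np.allclose(v.per_anchor, np.log(3))

    def test_clib_single_triple_identical(self):
        z = np.ones((3, 4))
        for tau in (0.07, 0.5, 1.0):
            v = clib_loss(emb(z, "three_view", 1), LossConfig(tau, "clib"))
            assert v.total == pytest.approx(np.log(2), abs=1e-12)

    def test_clib_opposed_background(self):
        """N=1, tau=1, sim(anchor,pos)=1, sim(anchor,bg)=-1 -> ln(1+e^-2)."""
        z = np.array([[1.0, 0.0], [1.0, 0.0], [-1.0, 0.0]])
        v = clib_loss(emb(z, "three_view", 1), LossConfig(1.0, "clib"))
        assert v.per_anchor[0] == pytest.approx(np.log(1 + np.exp(-2)), abs=1e-12)

    @pytest.mark.parametrize("n", [1, 2, 4, 8])
    @pytest.mark.parametrize("tau", [0.07, 0.5, 1.0])
    def test_uniform_similarity_closed_forms(self, n, tau):
        """All-equal pairwise similarities: CLIB anchor loss = ln(3N-1) and
        SimCLR anchor loss = ln(2N-1), independent of temperature."""
        z3 = np.tile(np.array([1.0, 1.0, 0.0]), (3 * n, 1))
        v3 = clib_loss(emb(z3, "three_view", n), LossConfig(tau, "clib"))
        assert np.allclose(v3.per_anchor, np.log(3 * n - 1), atol=1e-12)
        if n >= 1:
            z2 = np.tile(np.array([0.3, -0.7]), (2 * n, 1))
            v2 = simclr_loss(emb(z2, "two_view", n), LossConfig(tau, "simclr"))
            assert np.allclose(v2.per_anchor, np.log(2 * n - 1) if n > 1 else 0.0,
                               atol=1e-12)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_simclr_matches_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        z = rng.normal(size=(2 * n, int(rng.integers(3, 33))))
        tau = float(rng.uniform(0.05, 1.0))
        got = simclr_loss(emb(z, "two_view", n), LossConfig(tau, "simclr"))
        want_total, want_each = oracle_simclr(z, n, tau)
        assert got.total == pytest.approx(want_total, abs=1e-6)
        assert np.allclose(got.per_anchor, want_each, atol=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_clib_matches_double_loop(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(1, 9))
        z = rng.normal(size=(3 * n, int(rng.integers(3, 33))))
        tau = float(rng.uniform(0.05, 1.0))
        got = clib_loss(emb(z, "three_view", n), LossConfig(tau, "clib"))
        want_total, want_each = oracle_three_view(z, n, tau)
        assert got.total == pytest.approx(want_total, abs=1e-6)
        assert np.allclose(got.per_anchor, want_each, atol=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_ablation_matches_double_loop(self, seed):
        rng = np.random.default_rng(200 + seed)
        n = int(rng.integers(1, 9))
        z = rng.normal(size=(3 * n, int(rng.integers(3, 33))))
        tau = float(rng.uniform(0.05, 1.0))
        got = clib_ablation_loss(emb(z, "two_view_bg", n),
                                 LossConfig(tau, "clib_ablation"))
        want_total, want_each = oracle_three_view(z, n, tau)
        assert got.total == pytest.approx(want_total, abs=1e-6)
        assert np.allclose(got.per_anchor, want_each, atol=1e-6)


class TestReductionAndPermutation:
    def test_ablation_without_backgrounds_is_simclr(self):
        rng = np.random.default_rng(3)
        n = 4
        z = rng.normal(size=(3 * n, 16))
        e3 = emb(z, "two_view_bg", n)
        reduced = simclr_loss(drop_background(e3), LossConfig(0.07, "simclr"))
        direct = simclr_loss(emb(z[: 2 * n], "two_view", n), LossConfig(0.07, "simclr"))
        assert reduced.total == direct.total
        assert np.array_equal(reduced.per_anchor, direct.per_anchor)
        # extra background negatives can only enlarge every denominator
        full = clib_ablation_loss(e3, LossConfig(0.07, "clib_ablation"))
        assert np.all(full.per_anchor >= reduced.per_anchor)

    def test_interleaved_layout_bit_identical(self):
        rng = np.random.default_rng(4)
        n = 5
        z_block = rng.normal(size=(3 * n, 12))
        cfg = LossConfig(0.07, "clib")
        block_val = clib_loss(emb(z_block, "three_view", n), cfg)
        z_inter = z_block[block_to_interleaved(n)]
        inter_val = clib_loss_interleaved(z_inter, cfg)
        assert block_val.total == inter_val.total
        assert np.array_equal(block_val.per_anchor, inter_val.per_anchor)

    def test_interleaved_matches_triple_indexed_oracle(self):
        """Independent oracle written in the interleaved numbering: positives
        are consecutive (original, subject) rows of each triple, every triple's
        third row is background and never anchors."""
        rng = np.random.default_rng(5)
        n = 4
        tau = 0.07
        z = rng.normal(size=(3 * n, 8))
        pairs = []
        for k in range(n):
            pairs += [(3 * k, 3 * k + 1), (3 * k + 1, 3 * k)]
        denom = {i: [k for k in range(3 * n) if k != i] for i in range(3 * n)}
        want, _ = oracle_loss(z, pairs, denom, tau)
        got = clib_loss_interleaved(z, LossConfig(tau, "clib"))
        assert got.total == pytest.approx(want, abs=1e-6)

    def test_permutations_are_inverse(self):
        for n in (1, 3, 7):
            p, q = block_to_interleaved(n), interleaved_to_block(n)
            assert np.array_equal(p[q], np.arange(3 * n))


class TestInvariants:
    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_nonnegative_and_scale_invariant(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 6))
        z = rng.normal(size=(3 * n, 8))
        cfg = LossConfig(float(rng.uniform(0.05, 2.0)), "clib")
        v = clib_loss(emb(z, "three_view", n), cfg)
        assert v.total >= 0
        scaled = z * rng.uniform(0.1, 10.0, size=(3 * n, 1))
        v2 = clib_loss(emb(scaled, "three_view", n), cfg)
        assert v2.total == pytest.approx(v.total, abs=1e-9)

    def test_monotone_in_similarities(self):
        """Raising sim(anchor, positive) lowers the anchor loss; raising
        sim(anchor, background) increases it."""
        def anchor0_loss(pos_sim, bg_sim):
            ang_p, ang_b = np.arccos(pos_sim), np.arccos(bg_sim)
            z = np.array([[1.0, 0.0],
                          [np.cos(ang_p), np.sin(ang_p)],
                          [np.cos(ang_b), np.sin(ang_b)]])
            return clib_loss(emb(z, "three_view", 1), LossConfig(0.5, "clib")).per_anchor[0]

        assert anchor0_loss(0.9, 0.0) < anchor0_loss(0.5, 0.0)
        assert anchor0_loss(0.5, 0.5) > anchor0_loss(0.5, -0.5)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=(6, 5))
        for layout, n in [("three_view", 2), ("two_view", 3), ("two_view_bg", 2)]:
            total, _, dz = loss_and_grad(z, layout, n, 0.3)
            num = np.zeros_like(z)
            eps = 1e-6
            for i in range(z.shape[0]):
                for j in range(z.shape[1]):
                    zp, zm = z.copy(), z.copy()
                    zp[i, j] += eps
                    zm[i, j] -= eps
                    num[i, j] = (loss_and_grad(zp, layout, n, 0.3)[0]
                                 - loss_and_grad(zm, layout, n, 0.3)[0]) / (2 * eps)
            assert np.abs(num - dz).max() < 1e-7

    def test_config_validation(self):
        with pytest.raises(ValueError):
            LossConfig(temperature=-1.0)
        with pytest.raises(ValueError):
            LossConfig(variant="byol")
        z = np.ones((4, 3))
        with pytest.raises(ValueError):
            clib_loss(emb(z, "two_view", 2))  # wrong layout for variant
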