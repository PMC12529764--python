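"""Reward shaping and Monte-Carlo Q assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adseqgan.chemdata import TokenVocabulary
from adseqgan.generator import GeneratorPolicy
from adseqgan.rewards import (RewardConfig, compute_q, length_weight,
                              minmax_standardize, repetition_penalize)


class TestMinMax:
    def test_basic_mapping(self):
        assert minmax_standardize([2, 4, 6]).tolist() == [0.0, 0.5, 1.0]

    def test_constant_vector_maps_to_half(self):
        assert np.all(minmax_standardize([3.3, 3.3, 3.3]) == 0.5)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40))
    def test_unit_interval_and_argmax_preserved(self, values):
        out = minmax_standardize(values)
        assert np.all((out >= 0) & (out <= 1))
        assert int(np.argmax(out)) == int(np.argmax(values))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=20,
                    unique=True))
    def test_rank_order_preserved(self, values):
        out = minmax_standardize(values)
        order = np.argsort(values, kind="stable")
        assert np.all(np.diff(out[order]) >= 0)


class TestRepetitionPenalty:
    def test_four_copies_each_get_quarter(self):
        seqs = ["CCO"] * 4 + ["CCN"]
        r = repetition_penalize([0.8] * 4 + [0.6], seqs)
        assert np.allclose(r[:4], 0.2)
        assert r[4] == 0.6

    def test_unique_batch_unchanged(self):
        seqs = ["A", "B", "C"]
        r = repetition_penalize([0.1, 0.2, 0.3], seqs)
        assert r.tolist() == [0.1, 0.2, 0.3]

    def test_reward_mass_conserved_per_duplicate_group(self):
        seqs = ["X"] * 7
        r = repetition_penalize([0.7] * 7, seqs)
        assert r.sum() == pytest.approx(0.7)

    def test_token_array_sequences_supported(self):
        seqs = [np.array([1, 2, 3]), np.array([1, 2, 3]), np.array([4])]
        r = repetition_penalize([1.0, 1.0, 1.0], seqs)
        assert np.allclose(r, [0.5, 0.5, 1.0])


class TestLengthWeight:
    def test_matching_distribution_gives_unit_weights(self):
        ref = {10: 5, 20: 5}
        lengths = [10] * 5 + [20] * 5
        out, w = length_weight(np.ones(10), lengths, ref,
                               return_weights=True)
        assert np.allclose(w, 1.0)

    def test_unsupported_generated_lengths_hit_wmax(self):
        ref = {40: 100}
        lengths = [10] * 50
        _, w = length_weight(np.ones(50), lengths, ref, w_min=0.5,
                             w_max=2.0, return_weights=True)
        # generated mass sits where the reference has none -> down-weighted
        assert np.allclose(w, 0.5)

    def test_degenerate_clip_is_identity(self):
        ref = {10: 1, 30: 9}
        lengths = [10, 10, 30]
        out = length_weight(np.array([1.0, 2.0, 3.0]), lengths, ref,
                            w_min=1.0, w_max=1.0)
        assert np.allclose(out, [1.0, 2.0, 3.0])

    def test_empty_batch_noop(self):
        out = length_weight(np.zeros(0), [], {10: 1})
        assert out.size == 0


class TestRewardConfig:
    def test_lambda_simplex_enforced(self):
        with pytest.raises(ValueError):
            RewardConfig(lambda0=0.5, lambdas_aux=(0.8,))
        with pytest.raises(ValueError):
            RewardConfig(lambda0=-0.2, lambdas_aux=(1.2,))

    def test_rollout_count_positive(self):
        with pytest.raises(ValueError):
            RewardConfig(rollouts=0)


class _DetCritic:
    """Deterministic toy critic: score = 0.1 * sum(tokens before END)."""

    def __init__(self, vocab):
        self.vocab = vocab

    def key(self, row):
        out = []
        for tk in row:
            tk = int(tk)
            if tk == self.vocab.end:
                break
            if tk != self.vocab.pad:
                out.append(tk)
        return tuple(out)

    def score(self, seqs):
        return np.array([0.1 * sum(self.key(r)) % 1.0 for r in seqs])


def _det_aux(smiles, labels):
    return np.array([(sum(map(ord, s)) % 97) / 96.0 for s in smiles])


class TestComputeQ:
    def test_terminal_mix_arithmetic(self, toy_vocab):
        """Q(T) = lambda0*R_phi + lambda1*R_1 exactly, default weights."""
        pol = GeneratorPolicy(toy_vocab, embed_dim=8, hidden_dim=16,
                              max_length=4, seed=5)
        batch = pol.sample("X", 6, seed=9)
        crit = _DetCritic(toy_vocab)
        cfg = RewardConfig(lambda0=0.2, lambdas_aux=(0.8,), rollouts=2,
                           minmax=False, repetition_penalty=False)
        qb = compute_q(batch, pol, crit, [_det_aux], cfg, seed=1)
        for b in range(len(batch)):
            L = int(batch.lengths[b])
            row = batch.sequences[b]
            smi = toy_vocab.decode(row)
            expected = 0.2 * crit.score(row[None, :])[0] \
                + 0.8 * _det_aux([smi], None)[0]
            assert qb.q[b, L - 1] == pytest.approx(expected, abs=1e-12)

    def test_pure_adversarial_limit(self, toy_vocab):
        pol = GeneratorPolicy(toy_vocab, embed_dim=8, hidden_dim=16,
                              max_length=4, seed=5)
        batch = pol.sample("X", 4, seed=2)
        crit = _DetCritic(toy_vocab)
        cfg = RewardConfig(lambda0=1.0, lambdas_aux=(), rollouts=2,
                           minmax=True, repetition_penalty=False)
        qb = compute_q(batch, pol, crit, [], cfg, seed=3)
        from adseqgan.rewards import minmax_standardize as mm
        expect = mm(crit.score(batch.sequences))
        for b in range(len(batch)):
            L = int(batch.lengths[b])
            assert qb.q[b, L - 1] == pytest.approx(expect[b])

    def test_minmax_keeps_q_in_unit_interval(self, toy_vocab):
        pol = GeneratorPolicy(toy_vocab, embed_dim=8, hidden_dim=16,
                              max_length=4, seed=5)
        batch = pol.sample("X", 8, seed=4)
        crit = _DetCritic(toy_vocab)
        cfg = RewardConfig(rollouts=4, minmax=True,
                           repetition_penalty=False,
                           lambda0=0.2, lambdas_aux=(0.8,))
        qb = compute_q(batch, pol, crit, [_det_aux], cfg, seed=5)
        for b in range(len(batch)):
            L = int(batch.lengths[b])
            q = qb.q[b, :L]
            assert np.all((q >= -1e-12) & (q <= 1 + 1e-12))

    def test_mixing_linearity_in_aux_reward(self, toy_vocab):
        """Q is affine in each reward source at fixed rollouts (minmax off)."""
        pol = GeneratorPolicy(toy_vocab, embed_dim=8, hidden_dim=16,
                              max_length=4, seed=5)
        batch = pol.sample("X", 4, seed=6)
        crit = _DetCritic(toy_vocab)

        def aux_scaled(scale):
            return lambda s, l: scale * _det_aux(s, l)

        cfg = RewardConfig(lambda0=0.2, lambdas_aux=(0.8,), rollouts=16,
                           minmax=False, repetition_penalty=False)
        q1 = compute_q(batch, pol, crit, [aux_scaled(1.0)], cfg, seed=7)
        q2 = compute_q(batch, pol, crit, [aux_scaled(2.0)], cfg, seed=7)
        zero = compute_q(batch, pol, crit, [aux_scaled(0.0)], cfg, seed=7)
        # q2 - q1 == q1 - q0 elementwise (same rollout seed)
        assert np.allclose(q2.q - q1.q, q1.q - zero.q, atol=1e-9)

    def test_repetition_penalty_divides_full_rows(self, toy_vocab):
        pol = GeneratorPolicy(toy_vocab, embed_dim=8, hidden_dim=16,
                              max_length=2, seed=5)
        batch = pol.sample("X", 32, seed=8)
        crit = _DetCritic(toy_vocab)
        cfg_off = RewardConfig(lambda0=1.0, lambdas_aux=(), rollouts=1,
                               minmax=False, repetition_penalty=False)
        cfg_on = RewardConfig(lambda0=1.0, lambdas_aux=(), rollouts=1,
                              minmax=False, repetition_penalty=True)
        q_off = compute_q(batch, pol, crit, [], cfg_off, seed=9)
        q_on = compute_q(batch, pol, crit, [], cfg_on, seed=9)
        assert np.allclose(q_on.q, q_off.q / q_on.copies[:, None])
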