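"""Per-timestep reward assembly Q(t).

For a generated sequence Y_{1:T}, intermediate action values are Monte-Carlo
estimates: complete the prefix Y_{1:t} M times under the current policy and
average the mixed terminal reward

    Q(t) = (1/M) sum_m [ lambda_0 R_phi(Y^m) + sum_n lambda_n R_n(Y^m) ],  t < T
    Q(T) =            lambda_0 R_phi(Y)     + sum_n lambda_n R_n(Y)         (exact)

with the mixing weights on the simplex (sum lambda = 1).  Three shaping
mechanisms fight mode collapse: per-source min-max standardization to [0,1]
within each batch, dividing a duplicated sequence's reward by its copy
count, and re-weighting by the ratio of the real to the generated length
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RewardConfig:
    lambda0: float = 0.2            # adversarial weight; auxiliaries share the rest
    lambdas_aux: tuple = (0.8,)
    rollouts: int = 16              # M
    minmax: bool = True
    repetition_penalty: bool = True
    length_weight: bool = False
    lw_min: float = 0.5             # clip bounds for the length-weight ratio
    lw_max: float = 2.0
    lw_smooth: float = 1.0          # additive histogram smoothing
    rollout_stride: int = 1         # evaluate Q every `stride` tokens

    def __post_init__(self):
        lam = [self.lambda0, *self.lambdas_aux]
        if any(l < 0 for l in lam) or abs(sum(lam) - 1.0) > 1e-9:
            raise ValueError(f"lambda weights must be a simplex vector, got {lam}")
        if self.rollouts < 1:
            raise ValueError("rollout count M must be >= 1")


@dataclass
class RewardBatch:
    q: np.ndarray                    # (B, T) per-timestep rewards
    raw_critic: np.ndarray           # (B,) terminal critic scores
    raw_auxiliary: np.ndarray        # (B,) terminal auxiliary rewards
    copies: np.ndarray               # (B,) duplicate counts in batch
    length_w: np.ndarray             # (B,) applied length weights


def minmax_standardize(values) -> np.ndarray:
    """Map to [0,1] by (v - min)/(max - min); a constant vector maps to 0.5."""
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        return v
    lo, hi = v.min(), v.max()
    if hi - lo < 1e-12:
        return np.full_like(v, 0.5)
    return (v - lo) / (hi - lo)


def repetition_penalize(rewards, sequences) -> np.ndarray:
    """Divide each sequence's reward by its number of identical copies."""
    r = np.asarray(rewards, dtype=np.float64).copy()
    keys = [tuple(np.asarray(s).tolist()) if not isinstance(s, str) else s
            for s in sequences]
    counts = {}
    for k in keys:
        counts[k] = counts.get(k, 0) + 1
    return r / np.array([counts[k] for k in keys], dtype=np.float64)


def duplicate_counts(sequences) -> np.ndarray:
    keys = [tuple(np.asarray(s).tolist()) if not isinstance(s, str) else s
            for s in sequences]
    counts = {}
    for k in keys:
        counts[k] = counts.get(k, 0) + 1
    return np.array([counts[k] for k in keys], dtype=np.float64)


def length_weight(rewards, lengths, reference_hist: dict,
                  w_min=0.5, w_max=2.0, smooth=1.0,
                  return_weights=False):
    """Re-weight rewards by clip(p_data(L)/p_gen(L), w_min, w_max).

    ``reference_hist`` maps token length -> count in the real corpus.  Both
    histograms get additive smoothing over the union support before the
    ratio, so unseen generated lengths are clipped at w_max rather than
    dividing by zero.
    """
    r = np.asarray(rewards, dtype=np.float64)
    L = np.asarray(lengths)
    if r.size == 0:
        return (r, np.ones(0)) if return_weights else r
    support = sorted(set(reference_hist) | set(L.tolist()))
    ref = np.array([reference_hist.get(s, 0) for s in support], float) + smooth
    gen = np.array([(L == s).sum() for s in support], float) + smooth
    p_ref = ref / ref.sum()
    p_gen = gen / gen.sum()
    ratio = {s: float(np.clip(p_ref[i] / p_gen[i], w_min, w_max))
             for i, s in enumerate(support)}
    w = np.array([ratio[l] for l in L.tolist()])
    out = r * w
    if return_weights:
        return out, w
    return out


def terminal_reward(sequences, labels, policy, critic, auxiliaries,
                    config: RewardConfig, standardize=None):
    """Mixed terminal reward for completed padded sequences.

    ``auxiliaries`` is a list of callables (smiles_list, label_index) ->
    reward array in [0,1].  ``standardize`` overrides config.minmax (the
    t=T exact case in the oracle tests turns it off).  Returns
    (mixed, raw_critic, raw_aux_sum).
    """
    raw_c = np.asarray(critic.score(sequences), dtype=np.float64)
    smiles = [policy.vocab.decode(row) for row in sequences]
    std = config.minmax if standardize is None else standardize
    c = minmax_standardize(raw_c) if std else raw_c
    mixed = config.lambda0 * c
    raw_aux_total = np.zeros(len(smiles))
    for lam, aux in zip(config.lambdas_aux, auxiliaries):
        ra = np.asarray(aux(smiles, labels), dtype=np.float64)
        raw_aux_total += ra
        a = minmax_standardize(ra) if std else ra
        mixed = mixed + lam * a
    return mixed, raw_c, raw_aux_total


def compute_q(batch, policy, critic, auxiliaries, config: RewardConfig,
              seed: int | None = None, rng=None,
              reference_hist: dict | None = None) -> RewardBatch:
    """Monte-Carlo per-timestep rewards for a SampledBatch.

    For each checkpoint position t < T the batch's prefixes are completed
    M times under the policy, scored by the critic and auxiliaries, and
    averaged; intermediate positions between checkpoints inherit the next
    checkpoint's value.  Q(T) uses the actual sequence, no rollout.
    Shaping order: min-max (inside scoring) -> repetition penalty ->
    length weighting, the latter two applied uniformly across t.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    seqs = batch.sequences
    B, T = seqs.shape
    v = policy.vocab
    M = config.rollouts
    lengths = batch.lengths
    q = np.zeros((B, T), dtype=np.float64)

    # terminal rewards (exact, no rollout)
    final_mixed, raw_c, raw_aux = terminal_reward(
        seqs, batch.labels, policy, critic, auxiliaries, config)

    checkpoints = list(range(1, T, max(config.rollout_stride, 1)))
    cp_values = {}
    for t in checkpoints:
        active = lengths > t          # sequences still unfinished at t
        if not active.any():
            continue
        idx = np.where(active)[0]
        pref = seqs[idx, :t]
        rep_pref = np.repeat(pref, M, axis=0)
        rep_labels = np.repeat(batch.labels[idx], M)
        comp = policy.rollout_many(rep_pref,
                                   np.full(len(rep_pref), t),
                                   rep_labels, rng)
        mixed, _, _ = terminal_reward(comp, rep_labels, policy, critic,
                                      auxiliaries, config)
        cp_values[t] = (idx, mixed.reshape(len(idx), M).mean(axis=1))

    # fill the Q matrix: positions inherit the nearest checkpoint >= t,
    # the final position of each sequence gets the exact terminal value
    cp_sorted = sorted(cp_values)
    for b in range(B):
        L = int(lengths[b])
        for t in range(1, L):
            nxt = next((c for c in cp_sorted if c >= t), None)
            if nxt is not None and b in set(cp_values[nxt][0]) and nxt < L:
                pos = np.where(cp_values[nxt][0] == b)[0][0]
                q[b, t - 1] = cp_values[nxt][1][pos]
            else:
                q[b, t - 1] = final_mixed[b]
        q[b, L - 1] = final_mixed[b]

    copies = duplicate_counts([seqs[b, :lengths[b]] for b in range(B)])
    if config.repetition_penalty:
        q = q / copies[:, None]
    lw = np.ones(B)
    if config.length_weight and reference_hist:
        _, lw = length_weight(np.ones(B), lengths, reference_hist,
                              w_min=config.lw_min, w_max=config.lw_max,
                              smooth=config.lw_smooth, return_weights=True)
        q = q * lw[:, None]
    return RewardBatch(q=q, raw_critic=raw_c, raw_auxiliary=raw_aux,
                       copies=copies, length_w=lw)
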