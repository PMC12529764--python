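"""Wasserstein sequence critic.

A text-CNN (multi-width 1-D convolutions, max-over-time pooling, linear
head) scores token sequences with an unbounded real number; training
maximizes  E_real[score] - E_gen[score]  under a Lipschitz constraint
enforced by per-parameter weight clipping (gradient-penalty mode available).
Replacing the usual classification discriminator with this regression
contract is what makes the adversarial signal usable as a smooth RL reward.
"""

from __future__ import annotations

import numpy as np

from .chemdata import TokenVocabulary
from .nn import Adam, TextCNN

F32 = np.float32


class AdversarialCritic:
    def __init__(self, vocab: TokenVocabulary, embed_dim=32,
                 filter_widths=(2, 3, 4, 5), n_filters=32, max_length=80,
                 clip=0.01, gradient_penalty=0.0, seed=0, lr=5e-4):
        self.vocab = vocab
        self.clip = clip
        self.gradient_penalty = gradient_penalty
        self.net = TextCNN(len(vocab), embed_dim=embed_dim,
                           filter_widths=filter_widths, n_filters=n_filters,
                           max_len=max_length + 2, seed=seed)
        self.opt = Adam(self.net.params, lr=lr)

    def score(self, sequences: np.ndarray) -> np.ndarray:
        """Critic score per sequence; higher = more like real data."""
        return self.net.score(np.asarray(sequences, dtype=np.int64))

    def update(self, real_batch: np.ndarray, generated_batch: np.ndarray) -> float:
        """One ascent step on E_real[score] - E_gen[score].

        Returns the (pre-step) objective value.  With weight clipping, every
        parameter is clipped to [-c, c] after the step.
        """
        real = np.asarray(real_batch, dtype=np.int64)
        fake = np.asarray(generated_batch, dtype=np.int64)
        if len(real) == 0 or len(fake) == 0:
            raise ValueError("both batches must be nonempty")
        # gradient of -(mean(real) - mean(fake)) for a descent optimizer
        d_real = np.full(len(real), -1.0 / len(real))
        d_fake = np.full(len(fake), 1.0 / len(fake))
        sr, gr = self.net.score_grads(real, d_real)
        sf, gf = self.net.score_grads(fake, d_fake)
        grads = {k: gr[k] + gf[k] for k in gr}
        obj = float(sr.mean() - sf.mean())
        if not np.isfinite(obj):
            raise FloatingPointError("non-finite Wasserstein objective")
        if self.gradient_penalty > 0:
            # penalize squared embedding-gradient norm on real data
            _, gp = self.net.score_grads(real, np.full(len(real), 1.0 / len(real)))
            for k in grads:
                grads[k] += 2 * self.gradient_penalty * gp[k]
        self.opt.step(grads)
        if self.clip is not None and self.gradient_penalty == 0:
            self.net.clip_weights(self.clip)
        return obj


def pretrain_critic(critic: AdversarialCritic, corpus, policy, steps: int,
                    batch_size=64, seed=0) -> list[float]:
    """Run `steps` critic updates on fresh real/generated batches.

    Real batches are weighted draws from the corpus (honoring oversampling);
    negatives are sampled from the current policy with matched labels.
    Returns per-step objective values.
    """
    rng = np.random.default_rng(seed)
    v = critic.vocab
    objs = []
    for _ in range(steps):
        recs = corpus.sample_records(rng, batch_size)
        real = encode_padded([r.smiles for r in recs], v,
                             policy.max_length)
        labels = [r.label for r in recs]
        fakes = []
        for lab in sorted(set(labels)):
            k = sum(1 for l in labels if l == lab)
            fakes.append(policy.sample(lab, k, rng=rng).sequences)
        fake = pad_to_common(fakes, v.pad)
        real, fake = pad_pair(real, fake, v.pad)
        objs.append(critic.update(real, fake))
    return objs


# -- padding helpers -------------------------------------------------------

def encode_padded(smiles_list, vocab: TokenVocabulary, max_length: int):
    seqs = []
    for s in smiles_list:
        ids = vocab.encode(s)[:max_length] + [vocab.end]
        seqs.append(ids)
    T = max(len(s) for s in seqs)
    out = np.full((len(seqs), T), vocab.pad, dtype=np.int64)
    for i, s in enumerate(seqs):
        out[i, :len(s)] = s
    return out


def pad_to_common(mats, pad):
    T = max(m.shape[1] for m in mats)
    out = []
    for m in mats:
        if m.shape[1] < T:
            m = np.pad(m, ((0, 0), (0, T - m.shape[1])),
                       constant_values=pad)
        out.append(m)
    return np.concatenate(out, axis=0)


def pad_pair(a, b, pad):
    T = max(a.shape[1], b.shape[1])
    if a.shape[1] < T:
        a = np.pad(a, ((0, 0), (0, T - a.shape[1])), constant_values=pad)
    if b.shape[1] < T:
        b = np.pad(b, ((0, 0), (0, T - b.shape[1])), constant_values=pad)
    return a, b
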