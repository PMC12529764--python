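"""Class-conditional recurrent policy over SMILES tokens.

The policy G_theta is a single-layer LSTM shared across classes; the class
channel is a per-class start token plus (by default) an additive class
embedding at every step.  Training and sampling both run on padded integer
matrices; END is an absorbing terminal and generation stops at END or at
``max_length`` tokens.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass

import numpy as np

from .chemdata import LabeledCorpus, TokenVocabulary
from .nn import Adam, ConditionalLSTM, clip_grad_norm, _softmax

F32 = np.float32


@dataclass
class SampledBatch:
    """Token sequences (without start token), their labels and log-probs."""
    sequences: np.ndarray            # (B, T) int32, PAD-padded, END-terminated
    labels: np.ndarray               # (B,) int class indices
    logprobs: np.ndarray             # (B,) float per-sequence log-probability
    lengths: np.ndarray              # (B,) int incl. END token

    def __len__(self):
        return self.sequences.shape[0]


class GeneratorPolicy:
    """LSTM policy with MLE pretraining, seeded sampling and MC rollout."""

    def __init__(self, vocab: TokenVocabulary, embed_dim=32, hidden_dim=128,
                 max_length=80, class_embedding=True, seed=0, lr=3e-3):
        self.vocab = vocab
        self.max_length = max_length
        self.net = ConditionalLSTM(
            len(vocab), len(vocab.classes), embed_dim=embed_dim,
            hidden_dim=hidden_dim, class_embedding=class_embedding, seed=seed)
        self.opt = Adam(self.net.params, lr=lr)
        self.class_index = {c: i for i, c in enumerate(vocab.classes)}

    # ------------------------------------------------------------------
    def _encode_batch(self, records):
        """Teacher-forcing matrices: inputs start with START_<c>, targets
        end with END; mask marks real (non-pad) target positions."""
        v = self.vocab
        seqs = [v.encode(r.smiles) for r in records]
        labels = np.array([self.class_index[r.label] for r in records])
        T = min(max(len(s) for s in seqs) + 1, self.max_length + 1)
        B = len(seqs)
        inp = np.full((B, T), v.pad, dtype=np.int32)
        tgt = np.full((B, T), v.pad, dtype=np.int32)
        mask = np.zeros((B, T), dtype=F32)
        for b, (s, r) in enumerate(zip(seqs, records)):
            s = s[:self.max_length]
            inp[b, 0] = v.start(r.label)
            inp[b, 1:len(s) + 1] = s[:T - 1]
            tgt[b, :len(s)] = s[:T]
            if len(s) < T:
                tgt[b, len(s)] = v.end
            mask[b, :min(len(s) + 1, T)] = 1.0
        return inp, tgt, labels, mask

    def mle_pretrain(self, corpus: LabeledCorpus, epochs: int, batch_size=64,
                     seed=0, callback=None) -> list[float]:
        """Teacher-forced NLL training with weighted (oversampled) batches.

        Returns the per-epoch mean NLL (nats/token) over the sampled batches.
        """
        if epochs == 0:
            return []
        rng = np.random.default_rng(seed)
        n_batches = max(len(corpus) // batch_size, 1)
        history = []
        for ep in range(epochs):
            nlls = []
            for _ in range(n_batches):
                recs = corpus.sample_records(rng, batch_size)
                inp, tgt, labels, mask = self._encode_batch(recs)
                w = np.ones_like(mask)
                loss, grads, nll = self.net.weighted_nll_grads(
                    inp, tgt, labels, mask, w)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite MLE loss at epoch {ep}")
                clip_grad_norm(grads, 5.0)
                self.opt.step(grads)
                nlls.append(nll)
            history.append(float(np.mean(nlls)))
            if callback is not None:
                callback(ep, history[-1])
        return history

    def corpus_nll(self, corpus: LabeledCorpus) -> float:
        """Mean teacher-forced NLL in nats/token over a corpus."""
        inp, tgt, labels, mask = self._encode_batch(corpus.records)
        lp = self.net.sequence_logprob(inp, tgt, labels, mask)
        return float(-lp.sum() / mask.sum())

    # ------------------------------------------------------------------
    def sample(self, label: str, n: int, seed: int | None = None,
               rng: np.random.Generator | None = None) -> SampledBatch:
        """Draw n sequences conditioned on ``label``; seeded and reproducible."""
        if label not in self.class_index:
            raise KeyError(f"unknown class label {label!r}")
        if rng is None:
            rng = np.random.default_rng(seed)
        v = self.vocab
        li = self.class_index[label]
        labels = np.full(n, li, dtype=np.int64)
        if n == 0:
            return SampledBatch(np.zeros((0, 0), dtype=np.int32), labels,
                                np.zeros(0), np.zeros(0, dtype=np.int64))
        tok = np.full(n, v.start(label), dtype=np.int64)
        h, c = self.net.init_state(n)
        seqs = np.full((n, self.max_length + 1), v.pad, dtype=np.int32)
        logp = np.zeros(n, dtype=np.float64)
        done = np.zeros(n, dtype=bool)
        lengths = np.zeros(n, dtype=np.int64)
        for t in range(self.max_length + 1):
            h, c, probs = self.net.step_probs(tok, labels, h, c)
            probs = np.asarray(probs, dtype=np.float64)
            probs[:, v.pad] = 0.0
            if t == self.max_length:          # force termination
                nxt = np.full(n, v.end, dtype=np.int64)
            else:
                probs /= probs.sum(axis=1, keepdims=True)
                u = rng.random((n, 1))
                nxt = (probs.cumsum(axis=1) > u).argmax(axis=1)
            step_lp = np.log(np.maximum(
                probs[np.arange(n), nxt] / probs.sum(axis=1), 1e-12))
            logp = np.where(done, logp, logp + step_lp)
            nxt = np.where(done, v.pad, nxt)
            seqs[:, t] = np.where(done, v.pad, nxt)
            lengths = np.where(done, lengths, t + 1)
            done = done | (nxt == v.end)
            if done.all():
                seqs = seqs[:, :t + 1]
                break
            tok = np.where(done, v.end, nxt)
        return SampledBatch(seqs, labels, logp, lengths)

    def sample_smiles(self, label: str, n: int, seed=None, rng=None) -> list[str]:
        batch = self.sample(label, n, seed=seed, rng=rng)
        return [self.vocab.decode(row) for row in batch.sequences]

    # ------------------------------------------------------------------
    def rollout(self, prefix: np.ndarray, label_index: int, M: int,
                seed: int | None = None,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Complete ``prefix`` M times under the current policy.

        ``prefix`` is a 1-D int array of emitted tokens (no start token).
        Each completion begins with the prefix verbatim; if the prefix
        already ends with END, all completions equal the prefix.
        """
        prefix = np.asarray(prefix, dtype=np.int64)
        if prefix.ndim != 1 or len(prefix) < 1:
            raise ValueError("prefix must be a nonempty 1-D token array")
        if prefix.max(initial=0) >= len(self.vocab) or prefix.min(initial=0) < 0:
            raise ValueError("prefix contains tokens outside the vocabulary")
        if M < 1:
            raise ValueError("rollout count M must be >= 1")
        if rng is None:
            rng = np.random.default_rng(seed)
        v = self.vocab
        t0 = len(prefix)
        out = self.rollout_many(prefix[None, :].repeat(M, axis=0),
                                np.array([t0] * M),
                                np.full(M, label_index), rng)
        return out

    def rollout_many(self, prefixes: np.ndarray, prefix_lens: np.ndarray,
                     labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Vectorized rollout: each row of ``prefixes`` (padded) is completed
        once.  Returns a padded (B, <=max_length+1) completion matrix."""
        v = self.vocab
        B, P = prefixes.shape
        labels = np.asarray(labels, dtype=np.int64)
        h, c = self.net.init_state(B)
        start_toks = np.array([v.start(self.vocab.classes[li])
                               for li in labels], dtype=np.int64)
        # run the prefix through the network (teacher-forced)
        tok = start_toks
        out = np.full((B, self.max_length + 1), v.pad, dtype=np.int32)
        done = np.zeros(B, dtype=bool)
        for t in range(self.max_length + 1):
            h, c, probs = self.net.step_probs(tok, labels, h, c)
            in_prefix = t < prefix_lens
            if t < P:
                forced = prefixes[:, t]
            else:
                forced = np.full(B, v.pad, dtype=np.int64)
            if t == self.max_length:
                nxt = np.full(B, v.end, dtype=np.int64)
            else:
                p64 = np.asarray(probs, dtype=np.float64)
                p64[:, v.pad] = 0.0
                p64 /= p64.sum(axis=1, keepdims=True)
                u = rng.random((B, 1))
                nxt = (p64.cumsum(axis=1) > u).argmax(axis=1)
            nxt = np.where(in_prefix, forced, nxt)
            nxt = np.where(done, v.pad, nxt)
            out[:, t] = nxt
            done = done | (nxt == v.end)
            if done.all():
                out = out[:, :t + 1]
                break
            tok = np.where(done | (nxt == v.pad), v.end, nxt)
        return out

    def step1_distribution(self, label: str) -> np.ndarray:
        """Next-token distribution right after the start token."""
        li = self.class_index[label]
        h, c = self.net.init_state(1)
        _, _, probs = self.net.step_probs(
            np.array([self.vocab.start(label)]), np.array([li]), h, c)
        probs = np.asarray(probs[0], dtype=np.float64)
        probs[self.vocab.pad] = 0.0
        return probs / probs.sum()

    # ------------------------------------------------------------------
    def save(self, path):
        """Single-file checkpoint: parameters + vocabulary + config."""
        cfg = {"embed_dim": self.net.E, "hidden_dim": self.net.H,
               "max_length": self.max_length,
               "class_embedding": self.net.class_embedding,
               "classes": self.vocab.classes, "format_version": 1}
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("config.json", json.dumps(cfg))
            zf.writestr("vocab.txt", "\n".join(self.vocab.tokens))
            import io
            buf = io.BytesIO()
            np.savez(buf, **self.net.params)
            zf.writestr("params.npz", buf.getvalue())

    @classmethod
    def load(cls, path):
        import io
        with zipfile.ZipFile(path) as zf:
            cfg = json.loads(zf.read("config.json"))
            tokens = zf.read("vocab.txt").decode().split("\n")
            data = np.load(io.BytesIO(zf.read("params.npz")))
            params = {k: data[k] for k in data.files}
        vocab = TokenVocabulary.__new__(TokenVocabulary)
        vocab.classes = cfg["classes"]
        from .chemdata import PAD, END
        vocab.specials = [t for t in tokens
                          if t in (PAD, END) or t.startswith("START_")]
        vocab.tokens = tokens
        vocab.index = {t: i for i, t in enumerate(tokens)}
        policy = cls(vocab, embed_dim=cfg["embed_dim"],
                     hidden_dim=cfg["hidden_dim"],
                     max_length=cfg["max_length"],
                     class_embedding=cfg["class_embedding"])
        policy.net.set_weights(params)
        return policy
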