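"""Minimal NumPy neural-network primitives for the sequence GAN.

Two architectures live here: a class-conditional LSTM language model
(the generator policy) and a multi-width 1-D convolutional text network
with max-over-time pooling (the Wasserstein critic).  Both implement
manual reverse-mode gradients — the only losses ever needed are a
per-timestep *weighted* negative log-likelihood (weight 1 gives MLE
teacher forcing, weight Q(t) gives the REINFORCE surrogate) and the
Wasserstein mean-score difference, so a general autograd is unnecessary.

All parameters are float32; every source of randomness is an explicit
``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _uniform_init(rng: np.random.Generator, shape, scale=None):
    if scale is None:
        scale = 1.0 / np.sqrt(shape[0])
    return rng.uniform(-scale, scale, size=shape).astype(F32)


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for k, g in grads.items():
            if g is None:
                continue
            m = self.m[k] = b1 * self.m[k] + (1 - b1) * g
            v = self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            self.params[k] -= (lr_t * m / (np.sqrt(v) + self.eps)).astype(F32)


def clip_grad_norm(grads: dict, max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is <= max_norm."""
    total = float(np.sqrt(sum(float((g**2).sum()) for g in grads.values())))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / (total + 1e-12)
        for g in grads.values():
            g *= scale
    return total


class ConditionalLSTM:
    """Single-layer LSTM over token indices with additive class conditioning.

    The class channel enters twice: via a distinct start token (handled by
    the caller's vocabulary) and, when ``class_embedding`` is on, via an
    additive per-class embedding summed onto the token embedding at every
    step.
    """

    def __init__(self, vocab_size: int, n_classes: int, embed_dim=32,
                 hidden_dim=128, class_embedding=True, seed=0):
        self.V = vocab_size
        self.K = n_classes
        self.E = embed_dim
        self.H = hidden_dim
        self.class_embedding = class_embedding
        rng = np.random.default_rng(seed)
        E, H, V = embed_dim, hidden_dim, vocab_size
        self.params = {
            "emb": _uniform_init(rng, (V, E), 0.1),
            "cls": _uniform_init(rng, (n_classes, E), 0.1),
            "Wx": _uniform_init(rng, (E, 4 * H)),
            "Wh": _uniform_init(rng, (H, 4 * H)),
            "b": np.zeros(4 * H, dtype=F32),
            "Wy": _uniform_init(rng, (H, V)),
            "by": np.zeros(V, dtype=F32),
        }
        # forget-gate bias at 1 for stable early training
        self.params["b"][H:2 * H] = 1.0

    # ---- single step ------------------------------------------------
    def _embed(self, tokens, labels):
        x = self.params["emb"][tokens]
        if self.class_embedding:
            x = x + self.params["cls"][labels]
        return x

    def step(self, tokens, labels, h, c):
        """One forward step. tokens,labels: (B,) int; h,c: (B,H)."""
        p = self.params
        H = self.H
        x = self._embed(tokens, labels)
        z = x @ p["Wx"] + h @ p["Wh"] + p["b"]
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        c_new = f * c + i * g
        h_new = o * np.tanh(c_new)
        logits = h_new @ p["Wy"] + p["by"]
        return h_new, c_new, logits

    def init_state(self, batch):
        return (np.zeros((batch, self.H), dtype=F32),
                np.zeros((batch, self.H), dtype=F32))

    def step_probs(self, tokens, labels, h, c):
        h2, c2, logits = self.step(tokens, labels, h, c)
        return h2, c2, _softmax(logits)

    # ---- teacher-forced weighted NLL with full BPTT ------------------
    def weighted_nll_grads(self, inputs, targets, labels, mask, weights):
        """Forward + backward of  L = sum_t mask*w * (-log p(target_t)) / sum(mask).

        inputs, targets: (B,T) int arrays; mask, weights: (B,T) float.
        Returns (loss, grads, mean_nll) where mean_nll is the unweighted
        masked mean NLL per token (for reporting).
        """
        p = self.params
        B, T = inputs.shape
        H = self.H
        h = np.zeros((B, H), dtype=F32)
        c = np.zeros((B, H), dtype=F32)
        cache = []
        nll_sum = 0.0
        loss = 0.0
        probs_t = []
        for t in range(T):
            x = self._embed(inputs[:, t], labels)
            z = x @ p["Wx"] + h @ p["Wh"] + p["b"]
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            logits = h_new @ p["Wy"] + p["by"]
            pr = _softmax(logits)
            cache.append((x, h, c, i, f, g, o, c_new, tc, h_new, pr))
            probs_t.append(pr)
            h, c = h_new, c_new
        denom = max(float(mask.sum()), 1.0)
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dh_next = np.zeros((B, H), dtype=F32)
        dc_next = np.zeros((B, H), dtype=F32)
        rows = np.arange(B)
        for t in range(T - 1, -1, -1):
            x, h_prev, c_prev, i, f, g, o, c_new, tc, h_new, pr = cache[t]
            tgt = targets[:, t]
            logp = np.log(np.maximum(pr[rows, tgt], 1e-12))
            nll_sum += float(-(mask[:, t] * logp).sum())
            loss += float(-(mask[:, t] * weights[:, t] * logp).sum())
            # d loss / d logits
            w = (mask[:, t] * weights[:, t] / denom).astype(F32)[:, None]
            dlogits = pr * w
            dlogits[rows, tgt] -= w[:, 0]
            grads["Wy"] += h_new.T @ dlogits
            grads["by"] += dlogits.sum(axis=0)
            dh = dlogits @ p["Wy"].T + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g * g), do * o * (1 - o)], axis=1)
            grads["Wx"] += x.T @ dz
            grads["Wh"] += h_prev.T @ dz
            grads["b"] += dz.sum(axis=0)
            dh_next = dz @ p["Wh"].T
            dx = dz @ p["Wx"].T
            np.add.at(grads["emb"], inputs[:, t], dx)
            if self.class_embedding:
                np.add.at(grads["cls"], labels, dx)
        return loss / denom, grads, nll_sum / denom

    def sequence_logprob(self, inputs, targets, labels, mask):
        """Masked per-sequence log-probabilities (no gradients)."""
        B, T = inputs.shape
        h, c = self.init_state(B)
        rows = np.arange(B)
        lp = np.zeros(B, dtype=np.float64)
        for t in range(T):
            h, c, logits = self.step(inputs[:, t], labels, h, c)
            pr = _softmax(logits)
            lp += mask[:, t] * np.log(np.maximum(pr[rows, targets[:, t]], 1e-12))
        return lp

    def get_weights(self):
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, w):
        for k in self.params:
            self.params[k] = w[k].astype(F32).copy()


class TextCNN:
    """Multi-width 1-D conv net with max-over-time pooling and a linear head.

    Produces one unbounded real score per sequence — the Wasserstein
    critic contract.  Widths/filters follow standard text-CNN practice.
    """

    def __init__(self, vocab_size: int, embed_dim=32,
                 filter_widths=(2, 3, 4, 5), n_filters=32,
                 max_len=82, seed=0):
        self.V = vocab_size
        self.E = embed_dim
        self.widths = tuple(filter_widths)
        self.F = n_filters
        self.max_len = max_len
        rng = np.random.default_rng(seed)
        self.params = {"emb": _uniform_init(rng, (vocab_size, embed_dim), 0.1)}
        for w in self.widths:
            self.params[f"W{w}"] = _uniform_init(
                rng, (w * embed_dim, n_filters), 1.0 / np.sqrt(w * embed_dim))
            self.params[f"b{w}"] = np.zeros(n_filters, dtype=F32)
        total = n_filters * len(self.widths)
        self.params["Wo"] = _uniform_init(rng, (total, 1))
        self.params["bo"] = np.zeros(1, dtype=F32)

    def _forward(self, seqs):
        """seqs: (B,T) int, PAD-padded. Returns (scores, cache)."""
        B, T = seqs.shape
        if T > self.max_len:
            raise ValueError(
                f"sequence length {T} exceeds critic max length {self.max_len}")
        p = self.params
        emb = p["emb"][seqs]                      # (B,T,E)
        pooled, cache_w = [], {}
        for w in self.widths:
            n_win = T - w + 1
            if n_win < 1:
                # pad short batches up to the smallest usable window
                pad = np.zeros((B, w - T, self.E), dtype=F32)
                embw = np.concatenate([emb, pad], axis=1)
                n_win = 1
            else:
                embw = emb
            # im2col: (B, n_win, w*E)
            windows = np.stack(
                [embw[:, j:j + n_win, :] for j in range(w)], axis=2
            ).reshape(B, n_win, w * self.E)
            act = windows @ p[f"W{w}"] + p[f"b{w}"]     # (B,n_win,F)
            relu = np.maximum(act, 0)
            arg = relu.argmax(axis=1)                    # (B,F)
            mx = relu.max(axis=1)
            pooled.append(mx)
            cache_w[w] = (windows, act, arg)
        feat = np.concatenate(pooled, axis=1)            # (B, F*len)
        scores = (feat @ p["Wo"] + p["bo"])[:, 0]
        return scores, (seqs, emb, cache_w, feat)

    def score(self, seqs):
        return self._forward(seqs)[0]

    def score_grads(self, seqs, dscore):
        """Gradients of sum(dscore * score) w.r.t. parameters."""
        p = self.params
        scores, (seqs, emb, cache_w, feat) = self._forward(seqs)
        B, T = seqs.shape
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        ds = dscore.astype(F32)[:, None]                 # (B,1)
        grads["Wo"] = feat.T @ ds
        grads["bo"] = ds.sum(axis=0)
        dfeat = ds @ p["Wo"].T                           # (B,total)
        demb = np.zeros_like(emb)
        off = 0
        rows = np.arange(B)[:, None]
        cols = np.arange(self.F)[None, :]
        for w in self.widths:
            windows, act, arg = cache_w[w]
            dmx = dfeat[:, off:off + self.F]             # (B,F)
            off += self.F
            n_win = act.shape[1]
            dact = np.zeros_like(act)
            # route gradient through argmax (only where relu was active)
            active = act[rows, arg, cols] > 0
            dact[rows, arg, cols] = dmx * active
            grads[f"W{w}"] = np.einsum("bnk,bnf->kf", windows, dact)
            grads[f"b{w}"] = dact.sum(axis=(0, 1))
            dwin = dact @ p[f"W{w}"].T                   # (B,n_win,w*E)
            dwin = dwin.reshape(B, n_win, w, self.E)
            for j in range(w):
                upto = min(n_win, T - j)
                if upto > 0:
                    demb[:, j:j + upto, :] += dwin[:, :upto, j, :]
        np.add.at(grads["emb"], seqs, demb)
        return scores, grads

    def clip_weights(self, c: float):
        for k, v in self.params.items():
            np.clip(v, -c, c, out=v)

    def get_weights(self):
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, w):
        for k in self.params:
            self.params[k] = w[k].astype(F32).copy()
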