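"""Training orchestration for the full adversarial schedule.

Schedule: MLE pretraining of the policy (default 250 epochs), critic
pretraining (default 10 update steps), then alternating adversarial epochs
(default 50): per epoch, ``g_steps`` of {sample per class -> Monte-Carlo
Q(t) -> policy-gradient ascent} followed by ``d_steps`` Wasserstein critic
updates.  The auxiliary classifier is frozen throughout.  Every random draw
flows from the config seed, so identical configs reproduce identical epoch
reports byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .adversarial_critic import (AdversarialCritic, encode_padded, pad_pair,
                                 pretrain_critic)
from .auxiliary import AuxiliaryClassifier, auxiliary_reward_batch
from .chemdata import LabeledCorpus, TokenVocabulary, oversample
from .generator import GeneratorPolicy, SampledBatch
from .nn import clip_grad_norm
from .rewards import RewardBatch, RewardConfig, compute_q
from . import evaluation

F32 = np.float32


@dataclass
class TrainingConfig:
    mle_epochs: int = 250
    critic_pretrain_steps: int = 10
    adversarial_epochs: int = 50
    g_steps: int = 1
    d_steps: int = 5
    batch_size: int = 64
    oversample_factors: dict = field(default_factory=dict)
    reward: RewardConfig = field(default_factory=RewardConfig)
    seed: int = 0
    embed_dim: int = 32
    hidden_dim: int = 128
    max_length: int = 80
    g_lr: float = 3e-3
    d_lr: float = 5e-4
    grad_clip: float = 5.0
    n_eval: int = 256              # samples per class for epoch metrics
    checkpoint_every: int = 5

    def to_dict(self):
        d = asdict(self)
        return d


@dataclass
class EpochReport:
    epoch: int
    validity: dict                 # per class
    uniqueness: dict
    yields: dict
    mean_length: dict
    sd_length: dict
    responsiveness: dict
    critic_objective: float
    mean_q: float

    def row(self):
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


def policy_gradient_step(policy: GeneratorPolicy, batch: SampledBatch,
                         q: RewardBatch | np.ndarray, lr=None,
                         grad_clip=5.0) -> float:
    """One REINFORCE ascent step:  (1/T) sum_t grad log G(y_t|Y_<t) Q(t).

    Implemented as a weighted NLL descent where the per-position weight is
    Q(t); zero Q gives an exactly zero gradient.  Returns the surrogate
    loss (mean of -Q(t) log G over real positions).
    """
    qmat = q.q if isinstance(q, RewardBatch) else np.asarray(q, float)
    seqs = batch.sequences
    B, T = seqs.shape
    if qmat.shape != (B, T):
        raise ValueError("Q matrix misaligned with batch")
    v = policy.vocab
    # inputs: start token then the sequence shifted right
    inp = np.full((B, T), v.pad, dtype=np.int32)
    starts = np.array([v.start(policy.vocab.classes[li])
                       for li in batch.labels], dtype=np.int32)
    inp[:, 0] = starts
    inp[:, 1:] = seqs[:, :-1]
    mask = np.zeros((B, T), dtype=F32)
    for b in range(B):
        mask[b, :batch.lengths[b]] = 1.0
    loss, grads, _ = policy.net.weighted_nll_grads(
        inp, seqs, batch.labels, mask, qmat.astype(F32))
    if not all(np.isfinite(g).all() for g in grads.values()):
        raise FloatingPointError("non-finite policy gradient")
    clip_grad_norm(grads, grad_clip)
    if lr is not None:
        policy.opt.lr = lr
    policy.opt.step(grads)
    return float(loss)


def surrogate_loss(policy: GeneratorPolicy, batch: SampledBatch,
                   qmat: np.ndarray) -> float:
    """Surrogate value at fixed parameters (no update); linear in Q."""
    v = policy.vocab
    seqs = batch.sequences
    B, T = seqs.shape
    inp = np.full((B, T), v.pad, dtype=np.int32)
    inp[:, 0] = np.array([v.start(policy.vocab.classes[li])
                          for li in batch.labels])
    inp[:, 1:] = seqs[:, :-1]
    mask = np.zeros((B, T), dtype=F32)
    for b in range(B):
        mask[b, :batch.lengths[b]] = 1.0
    lp = np.zeros((B, T))
    h, c = policy.net.init_state(B)
    rows = np.arange(B)
    from .nn import _softmax
    for t in range(T):
        h, c, logits = policy.net.step(inp[:, t], batch.labels, h, c)
        pr = _softmax(logits)
        lp[:, t] = np.log(np.maximum(pr[rows, seqs[:, t]], 1e-12))
    denom = max(float(mask.sum()), 1.0)
    return float(-(mask * qmat * lp).sum() / denom)


def classifier_hash(clf: AuxiliaryClassifier) -> str:
    """Hash of the frozen classifier's decision-relevant state."""
    h = hashlib.sha256()
    h.update(json.dumps(clf.selected_features).encode())
    h.update(json.dumps(sorted(clf.medians.items())).encode())
    for est in clf.forest.estimators_:
        h.update(est.tree_.value.tobytes())
    return h.hexdigest()


def train_adseqgan(corpus: LabeledCorpus, config: TrainingConfig,
                   classifier: AuxiliaryClassifier,
                   out_dir: str | Path | None = None,
                   policy: GeneratorPolicy | None = None,
                   progress=None):
    """Run the full schedule; returns (policy, critic, reports).

    ``policy`` may carry a pre-pretrained generator (mle_epochs then applies
    on top only if > 0 and the policy was freshly built here).
    """
    if set(classifier.classes) != set(corpus.classes):
        raise ValueError(
            f"class sets differ: corpus {sorted(corpus.classes)} vs "
            f"classifier {sorted(classifier.classes)}")
    rng = np.random.default_rng(config.seed)
    if config.oversample_factors:
        corpus = oversample(corpus, config.oversample_factors)
    vocab = TokenVocabulary.from_corpus(corpus)
    fresh = policy is None
    if fresh:
        policy = GeneratorPolicy(vocab, embed_dim=config.embed_dim,
                                 hidden_dim=config.hidden_dim,
                                 max_length=config.max_length,
                                 seed=config.seed, lr=config.g_lr)
    critic = AdversarialCritic(policy.vocab, embed_dim=config.embed_dim,
                               max_length=config.max_length,
                               seed=config.seed + 1, lr=config.d_lr)
    auxiliaries = [lambda smiles, labels, _c=classifier:
                   _aux_for_labels(_c, smiles, labels, policy)]
    ref_hist = _pooled_length_hist(corpus)

    if fresh and config.mle_epochs > 0:
        policy.mle_pretrain(corpus, config.mle_epochs,
                            batch_size=config.batch_size,
                            seed=int(rng.integers(2**31)),
                            callback=progress)
    if config.critic_pretrain_steps > 0:
        pretrain_critic(critic, corpus, policy,
                        config.critic_pretrain_steps,
                        batch_size=config.batch_size,
                        seed=int(rng.integers(2**31)))

    reports = [evaluate_epoch(0, policy, classifier, corpus, config,
                              critic_obj=0.0, mean_q=0.0,
                              seed=int(rng.integers(2**31)))]
    out_dir = Path(out_dir) if out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "config.json").write_text(
            json.dumps(config.to_dict(), indent=2, default=str))

    labels_sorted = sorted(corpus.classes)
    for ep in range(1, config.adversarial_epochs + 1):
        mean_q = 0.0
        for _ in range(config.g_steps):
            per = max(config.batch_size // len(labels_sorted), 1)
            batches = []
            for lab in labels_sorted:
                batches.append(policy.sample(lab, per, rng=rng))
            batch = _merge_batches(batches, policy.vocab.pad)
            qb = compute_q(batch, policy, critic, auxiliaries,
                           config.reward, rng=rng,
                           reference_hist=ref_hist
                           if config.reward.length_weight else None)
            policy_gradient_step(policy, batch, qb,
                                 grad_clip=config.grad_clip)
            mean_q = float(np.mean([qb.q[b, :batch.lengths[b]].mean()
                                    for b in range(len(batch))]))
        critic_obj = 0.0
        for _ in range(config.d_steps):
            recs = corpus.sample_records(rng, config.batch_size)
            real = encode_padded([r.smiles for r in recs], policy.vocab,
                                 policy.max_length)
            fake_parts = [policy.sample(lab, max(
                config.batch_size // len(labels_sorted), 1),
                rng=rng).sequences for lab in labels_sorted]
            from .adversarial_critic import pad_to_common
            fake = pad_to_common(fake_parts, policy.vocab.pad)
            real, fake = pad_pair(real, fake, policy.vocab.pad)
            critic_obj = critic.update(real, fake)
        reports.append(evaluate_epoch(ep, policy, classifier, corpus,
                                      config, critic_obj=critic_obj,
                                      mean_q=mean_q,
                                      seed=int(rng.integers(2**31))))
        if out_dir and (ep % config.checkpoint_every == 0
                        or ep == config.adversarial_epochs):
            policy.save(out_dir / f"policy_ep{ep}.ckpt")
    if out_dir:
        with open(out_dir / "epoch_metrics.tsv", "w") as fh:
            for r in reports:
                fh.write(r.row() + "\n")
    return policy, critic, reports


def _aux_for_labels(classifier, smiles, labels, policy):
    """Auxiliary reward where each row's target is its own intended class."""
    labels = np.asarray(labels)
    out = np.zeros(len(smiles))
    for li in np.unique(labels):
        lab = policy.vocab.classes[int(li)]
        idx = np.where(labels == li)[0]
        out[idx] = auxiliary_reward_batch(
            classifier, [smiles[i] for i in idx], lab)
    return out


def _pooled_length_hist(corpus):
    hist = {}
    for c, st in corpus.length_stats().items():
        for l, n in st["histogram"].items():
            hist[l] = hist.get(l, 0) + n
    return hist


def _merge_batches(batches, pad):
    T = max(b.sequences.shape[1] for b in batches)
    seqs, labels, logp, lens = [], [], [], []
    for b in batches:
        s = b.sequences
        if s.shape[1] < T:
            s = np.pad(s, ((0, 0), (0, T - s.shape[1])), constant_values=pad)
        seqs.append(s)
        labels.append(b.labels)
        logp.append(b.logprobs)
        lens.append(b.lengths)
    return SampledBatch(np.concatenate(seqs), np.concatenate(labels),
                        np.concatenate(logp), np.concatenate(lens))


def evaluate_epoch(epoch, policy, classifier, corpus, config,
                   critic_obj=0.0, mean_q=0.0, seed=0) -> EpochReport:
    """Per-epoch generation metrics on n_eval samples per class."""
    rng = np.random.default_rng(seed)
    validity, uniqueness, yields = {}, {}, {}
    mean_len, sd_len, resp = {}, {}, {}
    per_label_smiles = {}
    for lab in sorted(corpus.classes):
        batch = policy.sample(lab, config.n_eval, rng=rng)
        smiles = [policy.vocab.decode(row) for row in batch.sequences]
        per_label_smiles[lab] = smiles
        ver, uniq = evaluation.validity_and_uniqueness(smiles)
        validity[lab] = ver
        uniqueness[lab] = uniq
        yields[lab] = evaluation.class_yield(smiles, classifier, lab)
        lens = np.maximum(batch.lengths - 1, 0)  # token count excl. END
        mean_len[lab] = float(np.mean(lens)) if len(lens) else 0.0
        sd_len[lab] = float(np.std(lens)) if len(lens) else 0.0
    labs = sorted(corpus.classes)
    for a in labs:
        others = [b for b in labs if b != a]
        b = others[0]
        ya = yields[a]
        yb = evaluation.class_yield(per_label_smiles[b], classifier, a)
        resp[a] = evaluation.log10_ratio(ya, yb)
    return EpochReport(epoch=epoch, validity=validity, uniqueness=uniqueness,
                       yields=yields, mean_length=mean_len, sd_length=sd_len,
                       responsiveness=resp, critic_objective=float(critic_obj),
                       mean_q=float(mean_q))
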