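# Methods

## Model

The generator `G_θ` is a single-layer LSTM language model over SMILES
tokens (token embedding 32, hidden state 128, softmax head), shared across
classes.  Class conditioning enters twice: each sequence is prompted with a
distinct `START_<c>` token, and a per-class embedding is added to the token
embedding at every step.  The additive embedding is the stronger channel —
SMILES canonicalization often moves class-discriminative substructures away
from the string start, so a start-token-only prompt can wash out over long
sequences; a config flag (`class_embedding=False`) restores the
start-token-only variant.  Generation stops at the END token or at 80
tokens, matching the 10–80-token corpus window.

The adversarial critic `D_φ` is a text CNN: embeddings, 1-D convolutions of
widths {2,3,4,5} with 32 filters each, max-over-time pooling, and a linear
head producing one unbounded real score per sequence.  It is trained on the
Wasserstein-1 objective `max E_real[score] − E_gen[score]`; turning
discrimination into regression gives the policy a smooth, non-saturating
reward.  The Lipschitz constraint uses per-parameter weight clipping
(c = 0.01 by default), the simplest control that is well-defined for
discrete inputs; a gradient-penalty mode exists in config.

The auxiliary discriminator is built once before adversarial training and
frozen.  For every corpus molecule the full RDKit descriptor block
(~210 physicochemical/topological/electronic descriptors) or the 166-key
MACCS fingerprint is computed.  In descriptor mode, each feature is scored
alone by 5-fold cross-validated logistic-regression AUC (direction-free:
`max(AUC, 1−AUC)`), features are ranked, the top 50 form a candidate pool
and the best k are kept (k = 18 by default; k = 12 is the preset for harder,
CNS-style boundaries).  A 100-tree random forest is fit on the selected,
median-imputed features.  The artifact stores feature names, imputation
medians, class order and rule thresholds, so scoring is reproducible
without the training data.

### Structural score

A physics-motivated multiplicative rule set maps each valid molecule to
[0, 1], starting from 1.0:

| rule | trigger | factor |
|---|---|---|
| heteroatom excess | (N+O+S)/heavy > 0.5 | ×0.5 |
| macrocycle | any ring ≥ 9 atoms | ×0.5 |
| antiaromatic ring | non-aromatic alternating 4- or 8-carbocycle | ×0.5 |
| halogen excess | halogens/heavy > 0.35 | 0 (reject) |
| carbon dominance | all-carbon skeleton, ≥ 12 heavy atoms | 0 (reject) |
| fused-aromatic bonus | ≥ 2 fused aromatic rings with N/O | ×1.2 |

The final value is clipped to [0, 1].  Two consequences of the clip are
deliberate: benzene (and any small unobjectionable molecule) scores exactly
1.0, and the fused-aromatic bonus only becomes visible when some penalty
has already lowered the score — the bonus rescues penalized-but-promising
scaffolds rather than inflating already-perfect ones.  The carbon-dominance
rejection carries a 12-heavy-atom floor so that benzene-sized hydrocarbons
are not rejected; "extremely carbon-dominant" is a property of larger
skeletons.

### Rewards

The auxiliary reward for a molecule asked to be class c is
`P(c|features) × structural` (probability mode) or
`1[P(c) > τ] × structural` with τ = 0.40 (threshold mode, for weak
classifiers).  Invalid SMILES receive auxiliary reward exactly 0 but still
receive the (standardized) critic reward — lightly broken strings still
carry learnable syntax signal, so zeroing their entire reward is
counterproductive.

Per-timestep action values use Monte-Carlo rollout: the prefix `Y_{1:t}` is
completed M times (M = 16 by default) under the current policy and the
mixed terminal reward `λ₀R_φ + λ₁R₁` is averaged; the final position uses
the actual sequence with no rollout.  Mixing weights lie on the simplex
with λ₀ = 0.2 on the adversarial channel — the auxiliary channel carries
most of the signal, which is the point of the architecture.  Reward shaping
is applied in the order: min-max standardization (per source, per batch;
constant batches map to the neutral 0.5) → repetition penalty → length
weighting.  Length weights are `clip(p_data(L)/p_gen(L), 0.5, 2.0)` with
additive smoothing over the union support, recomputed per batch.

Rollouts may be evaluated every `stride` tokens (`rollout_stride`,
default 1); positions between checkpoints inherit the next checkpoint's
value.  The estimator-vs-enumeration equivalence tests always run at
stride 1.

### Training schedule

MLE pretraining (teacher-forced NLL, Adam lr 3e-3, gradient-norm clip 5),
then 10 critic pretraining updates, then alternating adversarial epochs:
`g_steps` of {sample per class → compute Q → REINFORCE ascent} followed by
`d_steps = 5` critic updates.  The classifier is frozen throughout
(verified by hashing its trees before/after).  Oversampling is realized as
per-record sampling weights, so a factor-3 boost of a 548-vs-7728 minority
raises its expected batch share to 3·548/(3·548+7728) ≈ 0.175 without
copying records.

## Synthetic corpus

The fixture generator emulates the structure of the target task — two
chemically distinguishable classes sharing one token grammar — at desk
scale.  Class A molecules start from one of six fused aromatic N/O-
heterocycle scaffolds (quinoline, isoquinoline, quinazoline-like, indole,
benzimidazole, benzofuran) with aliphatic decorations appended; class B
molecules are aliphatic/ester chains with occasional cyclohexane rings and
an ~8% admixture of single phenyl rings so that descriptor separation is
strong (aromatic-ring AUC ≈ 1.0) but the chemistry is not single-feature
degenerate.  Output is valid by construction (template grammar, no
rejection loop for validity), canonicalized, de-duplicated, length-windowed
— it passes the preprocessing filters with zero removals.  Per-class token
lengths are Normal(34, 7) and Normal(28, 7) clipped to [10, 80].

What it does *not* emulate: stereochemistry, charged/bracket-atom-rich
species, ring-system diversity beyond the template set, and the heavy class
imbalance of real curation (the fixture is balanced; imbalance enters
through the oversampling tests).  Passing desk-scale tests therefore
demonstrates the mechanics of the method — conditioning, reward plumbing,
schedule, metrics — not chemical generalization to pharma corpora.

## Desk-scale problem sizes

The end-to-end checks and `scripts/acceptance.py` run 500 molecules/class,
20 MLE epochs, 10 critic steps, 5 adversarial epochs with `g_steps = 4`,
batch 64, M = 8, rollout stride 8, length weighting on; metrics use 256
samples/class per epoch and 2,000 samples per label for responsiveness.
These sizes give a clearly visible RL effect (validity and target-class
yield rise over the adversarial epochs; responsiveness stays strongly
positive) in a couple of CPU minutes.  `g_steps = 4` rather than the
library default 1 because with only 5 epochs, 20 generator updates are
needed for the yield trend to clear evaluation noise.

## Numerical choices

* float32 parameters/activations; float64 for probabilities during
  sampling and all reward arithmetic.
* Forget-gate bias initialized to 1; other weights uniform ±1/√fan-in.
* Softmax sampling excludes PAD and renormalizes; END is absorbing.
* Non-finite losses abort training immediately (no silent NaN runs).
* Min-max of a constant vector returns 0.5 (neutral, no divide-by-zero).
* Salt stripping keeps the fragment with most heavy atoms; ties break by
  lexicographic canonical SMILES, making curation deterministic.
* Feature selection treats a constant column as AUC 0.5, so it can never
  outrank an informative feature.
* Responsiveness is `log10(yield_a|a ÷ yield_a|b)`; a zero denominator
  yields an infinity sentinel in the API, and the acceptance script floors
  the denominator at one pseudo-hit (1/n) to keep JSON finite — the
  reported value is then a lower bound.

## Known limitations

* Weight clipping is a crude Lipschitz control; the critic's capacity is
  deliberately small and its scores are only used after per-batch
  standardization.
* REINFORCE without a baseline: min-max standardization and the repetition
  penalty substitute for variance reduction; desk-scale runs are stable but
  long schedules may benefit from more critic steps.
* Class membership of generated molecules is decided by the auxiliary
  classifier's argmax — yields are therefore relative to that classifier,
  not to an external assay.
* Different random seeds legitimately give different yields and scaffold
  mixes; comparisons across seeds should average, never assert equality.
* No stereochemistry handling, no 3-D geometry, no docking or
  pretrained-network metrics (e.g. FCD) — out of scope by design.
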