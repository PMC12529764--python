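"""Metrics on generated SMILES sets.

yield = unique_ratio * verified_ratio * class_ratio, where class membership
of a generated molecule is decided by the auxiliary classifier's argmax
(the only class oracle available at generation time).  Responsiveness for
class a is log10(yield_a given label a / yield_a given label b): positive
means the label channel steers generation.  Diversity is 1 - mean pairwise
ECFP4 (Morgan radius-2, 2048-bit) Tanimoto similarity.
"""

from __future__ import annotations

import math

import numpy as np
from rdkit import Chem
from rdkit import DataStructs
from rdkit.Chem import rdFingerprintGenerator

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)

INF_SENTINEL = float("inf")


def validity_and_uniqueness(smiles_list) -> tuple[float, float]:
    """(verified_ratio, unique_ratio): parseable fraction, and distinct
    canonical fraction among the parseable ones (0 if none parse)."""
    if not smiles_list:
        raise ValueError("empty SMILES list")
    canonical = []
    for s in smiles_list:
        mol = Chem.MolFromSmiles(s) if s else None
        if mol is not None:
            canonical.append(Chem.MolToSmiles(mol))
    verified = len(canonical) / len(smiles_list)
    unique = len(set(canonical)) / len(canonical) if canonical else 0.0
    return verified, unique


def class_ratio(smiles_list, classifier, target_label) -> float:
    """Fraction of unique valid molecules classified as the target class."""
    canonical = []
    for s in smiles_list:
        mol = Chem.MolFromSmiles(s) if s else None
        if mol is not None:
            canonical.append(Chem.MolToSmiles(mol))
    uniq = sorted(set(canonical))
    if not uniq:
        return 0.0
    proba, _ = classifier.predict_proba(uniq)
    col = classifier.class_column(target_label)
    pred = proba.argmax(axis=1)
    return float((pred == col).mean())


def class_yield(smiles_list, classifier, target_label) -> float:
    """unique_ratio * verified_ratio * class_ratio."""
    verified, unique = validity_and_uniqueness(smiles_list)
    if verified == 0.0 or unique == 0.0:
        return 0.0
    return unique * verified * class_ratio(smiles_list, classifier,
                                           target_label)


def log10_ratio(numerator: float, denominator: float) -> float:
    """log10(num/den) with an infinity sentinel for a zero denominator."""
    if denominator == 0.0:
        return INF_SENTINEL if numerator > 0 else 0.0
    if numerator == 0.0:
        return -INF_SENTINEL
    return math.log10(numerator / denominator)


def label_responsiveness(policy, classifier, label_a, label_b, n,
                         seed=0) -> float:
    """log10( yield_a(samples|label_a) / yield_a(samples|label_b) )."""
    rng = np.random.default_rng(seed)
    smi_a = policy.sample_smiles(label_a, n, rng=rng)
    smi_b = policy.sample_smiles(label_b, n, rng=rng)
    ya = class_yield(smi_a, classifier, label_a)
    yb = class_yield(smi_b, classifier, label_a)
    return log10_ratio(ya, yb)


def tanimoto_diversity(smiles_list, pair_cap=50000, seed=0):
    """(mean pairwise ECFP4 Tanimoto similarity, diversity = 1 - mean).

    Above ``pair_cap`` unordered pairs, a seeded random subset is scored.
    """
    mols = [Chem.MolFromSmiles(s) for s in smiles_list]
    mols = [m for m in mols if m is not None]
    if len(mols) < 2:
        raise ValueError("need >= 2 valid molecules")
    fps = [_MORGAN.GetFingerprint(m) for m in mols]
    n = len(fps)
    n_pairs = n * (n - 1) // 2
    sims = []
    if n_pairs <= pair_cap:
        for i in range(n - 1):
            sims.extend(DataStructs.BulkTanimotoSimilarity(fps[i],
                                                           fps[i + 1:]))
    else:
        rng = np.random.default_rng(seed)
        ii = rng.integers(0, n, size=pair_cap)
        jj = rng.integers(0, n - 1, size=pair_cap)
        jj = np.where(jj >= ii, jj + 1, jj)
        sims = [DataStructs.TanimotoSimilarity(fps[i], fps[j])
                for i, j in zip(ii, jj)]
    mean_sim = float(np.mean(sims))
    return mean_sim, 1.0 - mean_sim


def generation_report(smiles_list, classifier, target_label,
                      seed=0) -> dict:
    """Bundle of all metrics for one generated set (versioned schema)."""
    verified, unique = validity_and_uniqueness(smiles_list)
    cr = class_ratio(smiles_list, classifier, target_label)
    try:
        mean_sim, diversity = tanimoto_diversity(smiles_list, seed=seed)
    except ValueError:
        mean_sim, diversity = float("nan"), float("nan")
    lens = [len(s) for s in smiles_list if s]
    return {
        "schema_version": 1,
        "n_generated": len(smiles_list),
        "verified_ratio": verified,
        "unique_ratio": unique,
        "class_ratio": cr,
        "yield": unique * verified * cr,
        "mean_pairwise_tanimoto": mean_sim,
        "diversity": diversity,
        "length_mean": float(np.mean(lens)) if lens else 0.0,
        "length_sd": float(np.std(lens)) if lens else 0.0,
    }
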