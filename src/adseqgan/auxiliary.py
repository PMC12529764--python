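"""Pretrained auxiliary discriminator.

The auxiliary reward channel is a frozen, descriptor-based random-forest
classifier combined with a rule-based structural score.  The classifier is
built once, before adversarial training: compute RDKit molecular
descriptors (or MACCS keys), rank single-feature discriminative power by
5-fold cross-validated logistic-regression AUC, keep the top features, and
fit a 100-tree random forest on them.  At generation time the reward for a
molecule asked to be class c is

    R_n = P(c | features) * structural_score        (probability mode)
    R_n = 1[P(c | features) > tau] * structural_score  (threshold mode)

with tau defaulting to 0.40 in threshold mode — the regime used when the
classifier itself is weak (hard class boundaries, few minority samples).
Invalid SMILES never reach this module; they are assigned reward 0 upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

_DESC_FUNCS = dict(Descriptors.descList)


@dataclass
class DescriptorMatrix:
    values: pd.DataFrame          # rows: molecules, columns: named features
    mode: str                     # "descriptors" | "maccs"
    valid_mask: np.ndarray        # which input molecules produced a row


def compute_descriptors(molecules, mode="descriptors",
                        feature_names=None) -> DescriptorMatrix:
    """Compute a descriptor (or MACCS fingerprint) matrix.

    ``molecules`` may be RDKit mols or SMILES strings.  Invalid entries are
    flagged in ``valid_mask`` and excluded from the matrix.  Non-finite
    descriptor values are left as NaN here; imputation to training medians
    happens in the classifier.  Passing ``feature_names`` restricts
    computation to those descriptors (fast path for scoring).
    """
    mols, mask = [], []
    for m in molecules:
        if isinstance(m, str):
            m = Chem.MolFromSmiles(m)
        ok = m is not None
        mask.append(ok)
        if ok:
            mols.append(m)
    if mode == "maccs":
        rows = [np.array(MACCSkeys.GenMACCSKeys(m))[1:] for m in mols]
        cols = [f"maccs_{i}" for i in range(1, 167)]
        df = pd.DataFrame(rows, columns=cols, dtype=float)
    elif mode == "descriptors":
        names = list(feature_names) if feature_names else list(_DESC_FUNCS)
        data = {}
        for name in names:
            fn = _DESC_FUNCS[name]
            vals = []
            for m in mols:
                try:
                    v = float(fn(m))
                except Exception:
                    v = np.nan
                vals.append(v if np.isfinite(v) else np.nan)
            data[name] = vals
        df = pd.DataFrame(data)
    else:
        raise ValueError(f"unknown descriptor mode {mode!r}")
    return DescriptorMatrix(df, mode, np.array(mask, dtype=bool))


def select_features(X: pd.DataFrame, y, k=18, top_pool=50, seed=0,
                    manual=None, return_scores=False):
    """Rank features by single-variable logistic-regression 5-fold CV AUC.

    Each feature is scored alone: standardize, fit a logistic regression per
    stratified fold, average the held-out AUC.  Features are ranked, the top
    ``top_pool`` form the candidate pool, and the best ``k`` are returned in
    rank order.  A ``manual`` list short-circuits the selection.
    """
    if manual is not None:
        missing = set(manual) - set(X.columns)
        if missing:
            raise ValueError(f"manual features not in matrix: {missing}")
        return list(manual)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need >= 2 classes for feature selection")
    if k > X.shape[1]:
        raise ValueError("k exceeds feature count")
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    med = X.median(numeric_only=True)
    scores = {}
    for col in X.columns:
        x = X[col].fillna(med.get(col, 0.0)).to_numpy()[:, None]
        if np.nanstd(x) == 0:
            scores[col] = 0.5
            continue
        aucs = []
        for tr, te in skf.split(x, y):
            sc = StandardScaler().fit(x[tr])
            lr = LogisticRegression(max_iter=200)
            lr.fit(sc.transform(x[tr]), y[tr])
            proba = lr.predict_proba(sc.transform(x[te]))
            if proba.shape[1] == 2:
                aucs.append(roc_auc_score(y[te], proba[:, 1]))
            else:
                aucs.append(roc_auc_score(y[te], proba, multi_class="ovr"))
        # direction-free discriminative power
        a = float(np.mean(aucs))
        scores[col] = max(a, 1 - a)
    ranked = sorted(scores, key=lambda c: (-scores[c], c))
    pool = ranked[:top_pool]
    selected = pool[:k]
    if return_scores:
        return selected, scores
    return selected


# ---------------------------------------------------------------------------
# Structural rule set
# ---------------------------------------------------------------------------

@dataclass
class StructuralRuleSet:
    """Physics-motivated multiplicative rules; final score clipped to [0,1].

    Penalties halve the score, rejections zero it, and the fused-aromatic
    bonus (a heteroatom-bearing fused aromatic system) multiplies by 1.2
    before the final clip.  Thresholds are fractions of heavy atoms.
    """
    heteroatom_excess_frac: float = 0.5
    heteroatom_factor: float = 0.5
    macrocycle_min_size: int = 9
    macrocycle_factor: float = 0.5
    antiaromatic_factor: float = 0.5
    halogen_frac: float = 0.35
    carbon_dominance_frac: float = 0.95
    carbon_dominance_min_heavy: int = 12   # small all-carbon rings are fine
    fused_aromatic_bonus: float = 1.2


_HALOGENS = {"F", "Cl", "Br", "I"}


def _has_antiaromatic_ring(mol) -> bool:
    """Heuristic 4n-pi detection: a non-aromatic carbocycle of size 4 or 8
    whose in-ring double bonds alternate fully (cyclobutadiene-like)."""
    ri = mol.GetRingInfo()
    for ring in ri.BondRings():
        size = len(ring)
        if size not in (4, 8):
            continue
        bonds = [mol.GetBondWithIdx(i) for i in ring]
        if any(b.GetIsAromatic() for b in bonds):
            continue
        n_double = sum(1 for b in bonds
                       if b.GetBondType() == Chem.BondType.DOUBLE)
        if n_double == size // 2:
            return True
    return False


def _fused_aromatic_with_heteroatom(mol) -> bool:
    ri = mol.GetRingInfo()
    arom_rings = []
    for ring in ri.AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            arom_rings.append(set(ring))
    for i in range(len(arom_rings)):
        for j in range(i + 1, len(arom_rings)):
            if len(arom_rings[i] & arom_rings[j]) >= 2:   # share a bond
                atoms = arom_rings[i] | arom_rings[j]
                if any(mol.GetAtomWithIdx(a).GetSymbol() in ("N", "O")
                       for a in atoms):
                    return True
    return False


def structural_score(molecule, ruleset: StructuralRuleSet | None = None,
                     return_triggered=False):
    """Rule-based structural fitness in [0, 1].

    Starts at 1.0; each triggered rule multiplies its factor in; the result
    is clipped to [0, 1].  Returns (score, triggered_rule_names) when asked.
    """
    rs = ruleset or StructuralRuleSet()
    mol = Chem.MolFromSmiles(molecule) if isinstance(molecule, str) else molecule
    if mol is None:
        raise ValueError("structural_score requires a valid molecule")
    heavy = mol.GetNumHeavyAtoms()
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    n_c = symbols.count("C")
    n_nos = sum(symbols.count(s) for s in ("N", "O", "S"))
    n_hal = sum(1 for s in symbols if s in _HALOGENS)
    score = 1.0
    triggered = []

    if n_hal / max(heavy, 1) > rs.halogen_frac:
        triggered.append("halogen_rejection")
        score = 0.0
    if (heavy >= rs.carbon_dominance_min_heavy
            and n_c / max(heavy, 1) > rs.carbon_dominance_frac
            and n_c == heavy):
        triggered.append("carbon_dominance_rejection")
        score = 0.0
    if score > 0:
        if n_nos / max(heavy, 1) > rs.heteroatom_excess_frac:
            triggered.append("heteroatom_excess")
            score *= rs.heteroatom_factor
        if any(len(r) >= rs.macrocycle_min_size
               for r in mol.GetRingInfo().AtomRings()):
            triggered.append("macrocycle")
            score *= rs.macrocycle_factor
        if _has_antiaromatic_ring(mol):
            triggered.append("antiaromatic")
            score *= rs.antiaromatic_factor
        if _fused_aromatic_with_heteroatom(mol):
            triggered.append("fused_aromatic_bonus")
            score *= rs.fused_aromatic_bonus
    score = float(np.clip(score, 0.0, 1.0))
    if return_triggered:
        return score, triggered
    return score


# ---------------------------------------------------------------------------
# Classifier artifact
# ---------------------------------------------------------------------------

@dataclass
class AuxiliaryClassifier:
    forest: RandomForestClassifier
    selected_features: list
    medians: dict                      # feature -> training median
    classes: list
    mode: str                          # descriptor mode
    reward_mode: str = "probability"   # "probability" | "threshold"
    threshold: float = 0.40
    use_structural: bool = True
    ruleset: StructuralRuleSet = field(default_factory=StructuralRuleSet)
    cv_auc: float | None = None

    def features_for(self, molecules) -> tuple[np.ndarray, np.ndarray]:
        """Selected-feature matrix (imputed) + validity mask."""
        dm = compute_descriptors(
            molecules, mode=self.mode,
            feature_names=self.selected_features
            if self.mode == "descriptors" else None)
        X = dm.values[self.selected_features].copy()
        for c in self.selected_features:
            X[c] = X[c].fillna(self.medians[c])
        return X.to_numpy(), dm.valid_mask

    def predict_proba(self, molecules) -> tuple[np.ndarray, np.ndarray]:
        X, mask = self.features_for(molecules)
        if len(X) == 0:
            return np.zeros((0, len(self.classes))), mask
        return self.forest.predict_proba(X), mask

    def class_column(self, label) -> int:
        classes = list(self.forest.classes_)
        if label not in classes:
            raise KeyError(f"label {label!r} unknown to classifier")
        return classes.index(label)

    def save(self, path):
        joblib.dump(self, path)

    @classmethod
    def load(cls, path):
        return joblib.load(path)


def train_auxiliary_classifier(X: pd.DataFrame, y, selected_features=None,
                               mode="descriptors", seed=0, n_trees=100,
                               **artifact_kwargs):
    """Fit the 100-tree random forest on selected features.

    Returns (AuxiliaryClassifier, cv_auc) where cv_auc is the stratified
    5-fold cross-validated AUC on the training matrix.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need >= 2 classes to train the classifier")
    feats = list(selected_features) if selected_features else list(X.columns)
    Xs = X[feats].copy()
    medians = {c: float(np.nanmedian(Xs[c])) for c in feats}
    for c in feats:
        Xs[c] = Xs[c].fillna(medians[c])
    arr = Xs.to_numpy()
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(arr, y):
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                    n_jobs=1)
        rf.fit(arr[tr], y[tr])
        proba = rf.predict_proba(arr[te])
        if proba.shape[1] == 2:
            aucs.append(roc_auc_score(y[te], proba[:, 1]))
        else:
            aucs.append(roc_auc_score(y[te], proba, multi_class="ovr"))
    cv_auc = float(np.mean(aucs))
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                    n_jobs=1)
    forest.fit(arr, y)
    clf = AuxiliaryClassifier(forest=forest, selected_features=feats,
                              medians=medians,
                              classes=sorted(np.unique(y).tolist()),
                              mode=mode, cv_auc=cv_auc, **artifact_kwargs)
    return clf, cv_auc


def build_classifier_from_corpus(corpus, mode="descriptors", k=18, seed=0,
                                 **artifact_kwargs):
    """End-to-end: descriptors -> feature selection -> random forest."""
    smiles = [r.smiles for r in corpus.records]
    labels = [r.label for r in corpus.records]
    dm = compute_descriptors(smiles, mode=mode)
    y = np.array(labels)[dm.valid_mask]
    if mode == "descriptors":
        feats = select_features(dm.values, y, k=k, seed=seed)
    else:
        feats = list(dm.values.columns)
    return train_auxiliary_classifier(dm.values, y, selected_features=feats,
                                      mode=mode, seed=seed, **artifact_kwargs)


def auxiliary_reward(classifier: AuxiliaryClassifier, molecule, target_label,
                     ruleset: StructuralRuleSet | None = None) -> float:
    """Combined auxiliary reward R_n in [0, 1] for a single molecule."""
    return float(auxiliary_reward_batch(
        classifier, [molecule], target_label, ruleset=ruleset)[0])


def auxiliary_reward_batch(classifier: AuxiliaryClassifier, smiles_list,
                           target_label,
                           ruleset: StructuralRuleSet | None = None
                           ) -> np.ndarray:
    """Vectorized auxiliary reward; invalid SMILES get exactly 0."""
    col = classifier.class_column(target_label)
    rs = ruleset or classifier.ruleset
    mols = [Chem.MolFromSmiles(s) if isinstance(s, str) else s
            for s in smiles_list]
    valid = [m for m in mols if m is not None]
    out = np.zeros(len(smiles_list))
    if not valid:
        return out
    proba, _ = classifier.predict_proba(valid)
    p = proba[:, col]
    if classifier.reward_mode == "threshold":
        base = (p > classifier.threshold).astype(float)
    else:
        base = p
    if classifier.use_structural:
        struct = np.array([structural_score(m, rs) for m in valid])
        base = base * struct
    j = 0
    for i, m in enumerate(mols):
        if m is not None:
            out[i] = base[j]
            j += 1
    return out
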