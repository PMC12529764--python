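"""SMILES corpus handling: tokenization, preprocessing, oversampling, fixtures.

The corpus model is deliberately simple: a list of canonical-SMILES records,
each carrying a class label and a positive sampling weight (weights realize
minority-class oversampling).  Preprocessing mirrors standard generative-
chemistry curation: salt stripping, an organic-element whitelist, token-length
windowing, canonicalization and per-class de-duplication.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

PAD = "<pad>"
END = "<end>"

ALLOWED_ELEMENTS = frozenset(
    ["C", "H", "N", "O", "F", "Cl", "Br", "I", "B", "S", "P"])

MIN_TOKENS = 10
MAX_TOKENS = 80

# Multi-character units first: bracket atoms, %nn ring closures, two-letter
# organic-subset elements; then every single legal SMILES character.
_TOKEN_RE = re.compile(
    r"(\[[^\[\]]+\]|%\d{2}|Cl|Br|c|n|o|s|p|b|[BCNOFIPS]|[0-9]|"
    r"[=#\-\+\(\)/\\\.@:~\*\$])")


class TokenizationError(ValueError):
    """Raised when a SMILES string cannot be split into known tokens."""


def tokenize_smiles(s: str) -> list[str]:
    """Split a SMILES string into tokens.

    Two-letter elements (Cl, Br), bracket atoms ``[...]`` and two-digit ring
    closures ``%nn`` are single tokens; everything else is one character.
    Concatenating the result reproduces the input exactly.
    """
    if not s:
        raise TokenizationError("empty SMILES string")
    tokens = []
    pos = 0
    while pos < len(s):
        if s[pos] == "[":
            close = s.find("]", pos)
            if close < 0:
                raise TokenizationError(
                    f"unbalanced bracket at position {pos} in {s!r}")
        m = _TOKEN_RE.match(s, pos)
        if m is None:
            raise TokenizationError(
                f"unknown character {s[pos]!r} at position {pos} in {s!r}")
        tokens.append(m.group(0))
        pos = m.end()
    return tokens


def detokenize(tokens: list[str]) -> str:
    return "".join(tokens)


@dataclass
class SmilesRecord:
    smiles: str          # canonical form
    label: str
    weight: float = 1.0


class TokenVocabulary:
    """Bijective token<->index map with PAD, END and one START per class.

    Index 0 is always PAD; END follows; then one ``START_<c>`` per class in
    sorted order; then the corpus tokens in sorted order.
    """

    def __init__(self, tokens: list[str], classes: list[str]):
        self.classes = sorted(classes)
        self.specials = [PAD, END] + [f"START_{c}" for c in self.classes]
        body = sorted(set(tokens) - set(self.specials))
        self.tokens = self.specials + body
        self.index = {t: i for i, t in enumerate(self.tokens)}
        if len(self.index) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")

    def __len__(self):
        return len(self.tokens)

    @property
    def pad(self) -> int:
        return self.index[PAD]

    @property
    def end(self) -> int:
        return self.index[END]

    def start(self, label: str) -> int:
        try:
            return self.index[f"START_{label}"]
        except KeyError:
            raise KeyError(f"unknown class label {label!r}") from None

    def encode(self, smiles: str) -> list[int]:
        try:
            return [self.index[t] for t in tokenize_smiles(smiles)]
        except KeyError as e:
            raise TokenizationError(
                f"token {e.args[0]!r} not in vocabulary") from None

    def decode(self, ids) -> str:
        out = []
        for i in ids:
            t = self.tokens[int(i)]
            if t == END:
                break
            if t in self.index and not t.startswith("START_") and t != PAD:
                out.append(t)
        return "".join(out)

    @classmethod
    def from_corpus(cls, corpus: "LabeledCorpus") -> "TokenVocabulary":
        toks = []
        for r in corpus.records:
            toks.extend(tokenize_smiles(r.smiles))
        return cls(toks, sorted(corpus.classes))

    def save(self, path):
        with open(path, "w") as fh:
            for t in self.tokens:
                fh.write(t + "\n")

    @classmethod
    def load(cls, path):
        with open(path) as fh:
            tokens = [line.rstrip("\n") for line in fh if line.strip()]
        classes = [t[len("START_"):] for t in tokens if t.startswith("START_")]
        vocab = cls.__new__(cls)
        vocab.classes = classes
        vocab.specials = [t for t in tokens
                          if t in (PAD, END) or t.startswith("START_")]
        vocab.tokens = tokens
        vocab.index = {t: i for i, t in enumerate(tokens)}
        return vocab


@dataclass
class LabeledCorpus:
    records: list[SmilesRecord]
    classes: set[str] = field(default_factory=set)

    def __post_init__(self):
        if not self.classes:
            self.classes = {r.label for r in self.records}

    def __len__(self):
        return len(self.records)

    def by_class(self, label: str) -> list[SmilesRecord]:
        return [r for r in self.records if r.label == label]

    def length_stats(self) -> dict:
        """Per-class token-length mean/sd/histogram (recomputable)."""
        stats = {}
        for c in sorted(self.classes):
            lens = np.array([len(tokenize_smiles(r.smiles))
                             for r in self.by_class(c)])
            hist = Counter(lens.tolist())
            stats[c] = {"mean": float(lens.mean()) if len(lens) else 0.0,
                        "sd": float(lens.std()) if len(lens) else 0.0,
                        "histogram": dict(sorted(hist.items()))}
        return stats

    def sample_records(self, rng: np.random.Generator, n: int,
                       label: str | None = None) -> list[SmilesRecord]:
        """Weighted sampling with replacement, honoring record weights."""
        pool = self.records if label is None else self.by_class(label)
        w = np.array([r.weight for r in pool], dtype=np.float64)
        idx = rng.choice(len(pool), size=n, p=w / w.sum())
        return [pool[i] for i in idx]

    def save(self, path):
        with open(path, "w") as fh:
            fh.write("smiles,label,weight\n")
            for r in self.records:
                fh.write(f"{r.smiles},{r.label},{r.weight:g}\n")

    @classmethod
    def load(cls, path):
        import pandas as pd
        df = pd.read_csv(path)
        if "smiles" not in df.columns or "label" not in df.columns:
            raise ValueError("corpus file must have 'smiles' and 'label' columns")
        weights = df["weight"] if "weight" in df.columns else [1.0] * len(df)
        recs = [SmilesRecord(s, str(l), float(w))
                for s, l, w in zip(df["smiles"], df["label"], weights)]
        return cls(recs)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def _largest_organic_fragment(mol):
    """Keep the fragment with most heavy atoms; ties broken by canonical
    SMILES lexicographic order (deterministic salt stripping)."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol
    keyed = []
    for f in frags:
        try:
            Chem.SanitizeMol(f)
        except Exception:
            continue
        keyed.append((f.GetNumHeavyAtoms(), Chem.MolToSmiles(f), f))
    if not keyed:
        return None
    keyed.sort(key=lambda t: (-t[0], t[1]))
    return keyed[0][2]


def preprocess_corpus(raw, min_tokens=MIN_TOKENS, max_tokens=MAX_TOKENS,
                      verbose=False):
    """Curate raw (smiles, label) pairs into a LabeledCorpus.

    Filters, in order: parseability; salt stripping (largest organic
    fragment); element whitelist C/H/N/O/halogens/B/S/P; token-length window
    [min_tokens, max_tokens]; canonical de-duplication within class.
    Returns (corpus, removal_counts).
    """
    if not raw:
        raise ValueError("empty input corpus")
    removed = Counter()
    seen: set[tuple[str, str]] = set()
    records = []
    for item in raw:
        smiles, label = item[0], str(item[1])
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            removed["unparseable"] += 1
            continue
        mol = _largest_organic_fragment(mol)
        if mol is None:
            removed["unparseable"] += 1
            continue
        if any(a.GetSymbol() not in ALLOWED_ELEMENTS for a in mol.GetAtoms()):
            removed["element"] += 1
            continue
        can = Chem.MolToSmiles(mol)
        try:
            n_tok = len(tokenize_smiles(can))
        except TokenizationError:
            removed["tokenization"] += 1
            continue
        if not (min_tokens <= n_tok <= max_tokens):
            removed["length"] += 1
            continue
        key = (can, label)
        if key in seen:
            removed["duplicate"] += 1
            continue
        seen.add(key)
        records.append(SmilesRecord(can, label))
    if not records:
        raise ValueError("no records survived preprocessing")
    if verbose and removed:
        import sys
        print(f"preprocess: removed {dict(removed)}", file=sys.stderr)
    return LabeledCorpus(records), dict(removed)


def oversample(corpus: LabeledCorpus, factors: dict) -> LabeledCorpus:
    """Return a view with per-class sampling weights multiplied by `factors`.

    Under weighted sampling the expected frequency of class c scales by its
    factor: tripling a 548-molecule minority against 7,728 others raises its
    expected batch fraction to 3*548/(3*548+7728).
    """
    unknown = set(factors) - corpus.classes
    if unknown:
        raise ValueError(f"unknown classes in oversample factors: {unknown}")
    for f in factors.values():
        if f < 1:
            raise ValueError("oversample factors must be >= 1")
    recs = [SmilesRecord(r.smiles, r.label,
                         r.weight * factors.get(r.label, 1.0))
            for r in corpus.records]
    return LabeledCorpus(recs, set(corpus.classes))


# ---------------------------------------------------------------------------
# Synthetic fixture corpus
# ---------------------------------------------------------------------------

# Class A: fused aromatic N-heterocycle scaffolds (quinoline/indole-like).
_SCAFFOLDS_A = [
    "c1ccc2ncccc2c1",      # quinoline
    "c1ccc2cnccc2c1",      # isoquinoline
    "c1ccc2ncncc2c1",      # quinazoline-like
    "c1ccc2[nH]ccc2c1",    # indole
    "c1ccc2[nH]cnc2c1",    # benzimidazole
    "c1ccc2occc2c1",       # benzofuran
]

# chain growth units guaranteed to keep a linear SMILES valid
_CHAIN_ATOMS = ["C", "C", "C", "N", "O"]
_BRANCHES = ["(C)", "(CC)", "(O)", "(N)", "(=O)"]


def _grow_chain(rng, n_target_tokens, allow_ring=False, ester_bias=False):
    """Grow a random, guaranteed-valid aliphatic SMILES chain of roughly
    n_target_tokens tokens.  Heteroatoms are always followed by a carbon so
    no O-O / N-O adjacency appears; branches only ever decorate a carbon."""
    out = []
    ntok = 0
    prev_hetero = True  # force a leading carbon
    while ntok < n_target_tokens:
        if allow_ring and ntok + 8 <= n_target_tokens and rng.random() < 0.12:
            out.append("C1CCCCC1")
            ntok += 8
            prev_hetero = False
            continue
        if ester_bias and not prev_hetero and \
                ntok + 6 <= n_target_tokens and rng.random() < 0.2:
            out.append("C(=O)OC")
            ntok += 7
            prev_hetero = False
            continue
        atom = "C" if prev_hetero else _CHAIN_ATOMS[
            rng.integers(len(_CHAIN_ATOMS))]
        out.append(atom)
        ntok += 1
        prev_hetero = atom != "C"
        if atom == "C" and ntok + 4 <= n_target_tokens and rng.random() < 0.15:
            br = _BRANCHES[rng.integers(len(_BRANCHES))]
            out.append(br)
            ntok += len(br) - 2 + 2  # branch tokens incl. parens
            prev_hetero = False
    if out and out[-1] in ("O", "N"):
        out.append("C")
    return "".join(out)


def generate_fixture_corpus(n_per_class: dict, length_range=(10, 80),
                            seed: int = 0,
                            length_means: dict | None = None,
                            length_sds: dict | None = None) -> LabeledCorpus:
    """Generate a two-class synthetic SMILES corpus for desk-scale training.

    Class layout (template-based, valid by construction):

    * first class (sorted order) — fused aromatic N/O-heterocycle scaffolds
      with short aliphatic decorations appended after the scaffold, so the
      first token is always aromatic;
    * second class — aliphatic/ester-rich chains with occasional cyclohexane
      rings, starting with ``C``; a small fraction carries one phenyl ring so
      descriptor separation is strong but not degenerate.

    Every output passes :func:`preprocess_corpus` unchanged: molecules are
    emitted canonicalized, de-duplicated within class, with token lengths
    inside ``length_range``.  Byte-identical output for identical arguments.
    """
    if len(n_per_class) < 2:
        raise ValueError("need at least 2 classes")
    lo, hi = length_range
    if lo < MIN_TOKENS or hi > MAX_TOKENS or lo >= hi:
        raise ValueError(f"infeasible length_range {length_range} "
                         f"(grammar supports [{MIN_TOKENS},{MAX_TOKENS}])")
    classes = sorted(n_per_class)
    length_means = length_means or {}
    length_sds = length_sds or {}
    rng = np.random.default_rng(seed)
    records = []
    for ci, label in enumerate(classes):
        aromatic_class = ci == 0
        mean = length_means.get(label, 34.0 if aromatic_class else 28.0)
        sd = length_sds.get(label, 7.0)
        seen = set()
        guard = 0
        while len(seen) < n_per_class[label]:
            guard += 1
            if guard > 200 * n_per_class[label]:
                raise RuntimeError("fixture grammar failed to produce "
                                   "enough unique molecules")
            target = int(np.clip(round(rng.normal(mean, sd)), lo, hi))
            if aromatic_class:
                scaf = _SCAFFOLDS_A[rng.integers(len(_SCAFFOLDS_A))]
                budget = max(target - len(tokenize_smiles(scaf)) - 1, 2)
                tail = _grow_chain(rng, budget)
                smi = scaf + tail
            else:
                if rng.random() < 0.08 and target >= 18:
                    head = _grow_chain(rng, max(target - 9, 4))
                    smi = head + "c1ccccc1"
                else:
                    smi = _grow_chain(rng, target, allow_ring=True,
                                      ester_bias=True)
            mol = Chem.MolFromSmiles(smi)
            if mol is None:  # grammar guarantees validity; belt-and-braces
                continue
            can = Chem.MolToSmiles(mol)
            if not (lo <= len(tokenize_smiles(can)) <= hi):
                continue
            if can in seen:
                continue
            seen.add(can)
            records.append(SmilesRecord(can, label))
    return LabeledCorpus(records, set(classes))
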