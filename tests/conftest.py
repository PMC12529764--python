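import numpy as np
import pytest

from adseqgan.auxiliary import (build_classifier_from_corpus,
                                compute_descriptors, select_features)
from adseqgan.chemdata import TokenVocabulary, generate_fixture_corpus

FIXTURE_SEED = 7
N_PER_CLASS = 500


@pytest.fixture(scope="session")
def fixture_corpus():
    """The frozen desk-scale corpus: 500 molecules per class, seed 7."""
    return generate_fixture_corpus({"A": N_PER_CLASS, "B": N_PER_CLASS},
                                   seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def small_corpus():
    """A smaller corpus for fast unit tests."""
    return generate_fixture_corpus({"A": 120, "B": 120}, seed=3)


@pytest.fixture(scope="session")
def fixture_descriptors(fixture_corpus):
    smiles = [r.smiles for r in fixture_corpus.records]
    y = np.array([r.label for r in fixture_corpus.records])
    dm = compute_descriptors(smiles)
    return dm, y


@pytest.fixture(scope="session")
def fixture_selected_features(fixture_descriptors):
    dm, y = fixture_descriptors
    return select_features(dm.values, y, k=18, seed=0)


@pytest.fixture(scope="session")
def fixture_classifier(fixture_corpus):
    clf, auc = build_classifier_from_corpus(fixture_corpus, k=18, seed=0)
    clf._cv_auc_for_tests = auc
    return clf


@pytest.fixture(scope="session")
def micro_classifier(small_corpus):
    clf, _ = build_classifier_from_corpus(small_corpus, k=5, seed=0)
    return clf


@pytest.fixture(scope="session")
def toy_vocab():
    """3-token single-class vocabulary for enumerable rollout spaces."""
    return TokenVocabulary(["C", "N", "O"], ["X"])
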