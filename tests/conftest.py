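import numpy as np
import pytest

from mvhagcn.data_io import AssociationMatrix, EntityIndex
from mvhagcn.synthetic import SyntheticConfig, generate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """A small but structured bundle for protocol-level tests."""
    return generate_bundle(SyntheticConfig(n_mirna=30, n_disease=20, seed=11))


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_mirna=30, n_disease=20, seed=11)


@pytest.fixture(scope="session")
def default_bundle():
    return generate_bundle(SyntheticConfig(seed=1))


@pytest.fixture
def tiny_assoc():
    index = EntityIndex(("m1", "m2"), ("d1", "d2"))
    return AssociationMatrix(np.array([[1.0, 0.0], [0.0, 1.0]]), index)


def edit_distance_dp(a: str, b: str) -> int:
    """Brute-force dynamic-programming Levenshtein distance (test oracle)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return prev[len(b)]


def auc_concordance(scores, labels) -> float:
    """O(n^2) concordant-pair AUC with half credit for ties (test oracle)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))
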