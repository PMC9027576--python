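import numpy as np
import pandas as pd
import pytest

from pigsna.pedigree import Pedigree


@pytest.fixture
def trio_pedigree():
    """Sire, dam, two full-sib offspring."""
    return Pedigree(
        np.array([1, 2, 3, 4]), np.array([0, 0, 1, 1]), np.array([0, 0, 2, 2])
    )


@pytest.fixture
def inbred_pedigree():
    """Full sibs mated: offspring 5 has F = 1/4."""
    return Pedigree(
        np.array([1, 2, 3, 4, 5]),
        np.array([0, 0, 1, 1, 3]),
        np.array([0, 0, 2, 2, 4]),
    )


def random_pedigree(rng: np.random.Generator, n: int) -> Pedigree:
    """Random multi-generation pedigree; parents drawn among earlier animals."""
    sire = np.zeros(n, dtype=np.int64)
    dam = np.zeros(n, dtype=np.int64)
    n_founders = max(4, n // 5)
    for i in range(n_founders, n):
        if rng.random() < 0.15:  # occasional unknown parent
            continue
        s, d = rng.integers(0, i, size=2)
        sire[i] = s + 1
        if rng.random() >= 0.1:
            dam[i] = d + 1
    return Pedigree(np.arange(1, n + 1), sire, dam)


@pytest.fixture
def small_trait_table():
    """Minimal trait table with every fixed-effect column present."""
    rng = np.random.default_rng(7)
    n = 60
    return pd.DataFrame(
        {
            "animal": np.arange(1, n + 1),
            "pen": np.repeat(np.arange(6), 10),
            "litter": np.repeat(np.arange(12), 5),
            "sex": np.tile(["male", "female", "castrated"], n // 3),
            "line": np.tile(["Y", "YxL"], n // 2),
            "batch": np.repeat(np.arange(6), 10) % 3,
            "weight": rng.normal(28, 3, n).round(2),
            "trait": rng.normal(0, 1, n),
        }
    )
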