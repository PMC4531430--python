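from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from hcscnet import CountTable

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def mirna_table() -> CountTable:
    """2-pair miRNA toy table with an obvious 4-fold up feature (mir-b)."""
    return CountTable(
        feature_ids=("mir-a", "mir-b", "mir-c"),
        sample_ids=("s1-stem", "s1-cancer", "s2-stem", "s2-cancer"),
        counts=np.array(
            [
                [100, 100, 100, 100],
                [400, 100, 420, 95],
                [3, 3, 2, 4],
            ]
        ),
        library_sizes=np.array([10**6] * 4),
        feature_class="miRNA",
    )


@pytest.fixture
def gene_table() -> CountTable:
    return CountTable(
        feature_ids=("g1", "g2"),
        sample_ids=("s1-stem", "s1-cancer"),
        counts=np.array([[10, 40], [7, 7]]),
        library_sizes=np.array([10**6, 10**6]),
        feature_class="gene",
        feature_lengths=np.array([1000, 2500]),
    )


def random_count_table(rng: np.random.Generator, feature_class: str = "miRNA") -> CountTable:
    n_feat = int(rng.integers(1, 12))
    n_samp = int(rng.integers(1, 5))
    counts = rng.integers(0, 500, size=(n_feat, n_samp))
    lengths = rng.integers(100, 5000, size=n_feat) if feature_class == "gene" else None
    return CountTable(
        feature_ids=tuple(f"f{i}" for i in range(n_feat)),
        sample_ids=tuple(f"s{j}" for j in range(n_samp)),
        counts=counts,
        library_sizes=np.maximum(counts.sum(axis=0), 1),
        feature_class=feature_class,
        feature_lengths=lengths,
    )
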