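import numpy as np
import pandas as pd
import pytest

import coremicro as cm


@pytest.fixture
def toy_table() -> cm.CountTable:
    """3 OTUs x 2 samples with the literal counts used across format tests."""
    return cm.CountTable(
        ["otu1", "otu2", "otu3"], ["s1", "s2"], np.array([[5, 0], [1, 2], [0, 7]])
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small-but-structured synthetic multi-study dataset (session-scoped)."""
    spec = cm.SyntheticSpec(
        n_studies=10,
        samples_per_study=(14, 14),
        n_otus=160,
        n_core=24,
        n_subcore=4,
        core_mra_target=0.72,
        subcore_mra_target=0.16,
        depth_lognormal=(9.2, 0.3),
        seed=11,
    )
    return cm.generate_dataset(spec)


def random_count_table(rng, n_otus=6, n_samples=6, high=30) -> cm.CountTable:
    counts = rng.integers(0, high, size=(n_otus, n_samples))
    counts[0] += 1  # no all-zero samples
    return cm.CountTable(
        [f"o{i}" for i in range(n_otus)],
        [f"s{j}" for j in range(n_samples)],
        counts,
    )
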