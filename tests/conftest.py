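import numpy as np
import pandas as pd
import pytest

from seed2seedling import FeatureTable


@pytest.fixture
def toy_table() -> FeatureTable:
    """3 seed replicates, 1 soil sample, 2 root samples over 4 ASVs."""
    counts = pd.DataFrame(
        [[5, 0, 3, 0],
         [0, 0, 3, 0],
         [0, 0, 0, 0],
         [9, 9, 0, 2],
         [4, 1, 1, 0],
         [0, 2, 1, 0]],
        index=["seed_A", "seed_B", "seed_C", "soil_A", "root_A", "root_B"],
        columns=["a", "b", "c", "d"],
    )
    metadata = pd.DataFrame(
        {
            "compartment": ["seed", "seed", "seed", "soil", "root", "root"],
            "soil": [pd.NA, pd.NA, pd.NA, "S1", "S1", "S1"],
            "genotype": ["Boston"] * 3 + [pd.NA, "Boston", "Boston"],
            "year": ["Y1"] * 3 + [pd.NA, "Y1", "Y1"],
            "stage": [pd.NA] * 4 + ["d07", "d07"],
            "replicate": ["A", "B", "C", "A", "A", "B"],
        },
        index=counts.index,
    )
    return FeatureTable(counts, metadata)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_feature_table(rng: np.random.Generator, n_samples=6, n_asvs=10) -> FeatureTable:
    counts = pd.DataFrame(
        rng.integers(0, 30, size=(n_samples, n_asvs)),
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"asv{j}" for j in range(n_asvs)],
    )
    metadata = pd.DataFrame(
        {"compartment": rng.choice(["seed", "soil", "root", "stem"], size=n_samples)},
        index=counts.index,
    )
    return FeatureTable(counts, metadata)
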