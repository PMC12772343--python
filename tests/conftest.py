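import numpy as np
import pandas as pd
import pytest

from altigut import AbundanceTable, SynthConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_table():
    """3 taxa x 4 samples with known counts."""
    data = pd.DataFrame(
        [[2, 5, 0, 1], [2, 0, 0, 1], [4, 5, 3, 2]],
        index=pd.Index(["taxA", "taxB", "taxC"], name="feature_id"),
        columns=["s1", "s2", "s3", "s4"],
    )
    return AbundanceTable(data=data, rank="species")


@pytest.fixture
def phylum_table():
    data = pd.DataFrame(
        {"s1": [30.0, 10.0, 5.0], "s2": [20.0, 20.0, 2.0], "s3": [7.0, 0.0, 1.0]},
        index=pd.Index(["Bacillota", "Bacteroidota", "Pseudomonadota"], name="feature_id"),
    )
    return AbundanceTable(data=data, rank="phylum")


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset shared across tests (seed 42)."""
    return generate_dataset(SynthConfig(seed=42))
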