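import numpy as np
import pandas as pd
import pytest

from entropyscape.methylome_io import SampleMetadata
from entropyscape.synthetic import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort shared by read-only tests."""
    cfg = SimConfig(n_per_group=(12, 8, 10), n_segments=300, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture()
def tiny_meta():
    return SampleMetadata(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(6)],
        "group": ["LLI", "LLI", "elder", "elder", "younger", "younger"],
        "age": [101.0, 99.0, 75.0, 73.0, 60.0, 58.0],
        "batch": ["b1", "b2", "b1", "b2", "b1", "b2"],
    }))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
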