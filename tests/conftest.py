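import numpy as np
import pandas as pd
import pytest

from coexnet import preprocess
from coexnet.simulate import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def sim_data():
    """Default simulated experiment, seed 1 (counts, sample sheet, truth)."""
    return simulate_experiment(SimConfig(seed=1))


@pytest.fixture(scope="session")
def filtered_expression(sim_data):
    """Normalized, variance-stabilized expression of the top half of genes."""
    counts, sheet, _ = sim_data
    s = preprocess.estimate_size_factors(counts)
    x = preprocess.vst_transform(counts, s)
    return preprocess.filter_by_variance(x, percentile=50)


@pytest.fixture
def tiny_counts():
    """2 genes x 2 samples with hand-computable size factors."""
    return pd.DataFrame(
        {"s1": [2, 4], "s2": [4, 8]}, index=pd.Index(["g1", "g2"], name="gene_id")
    ).astype(float)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
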