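import numpy as np
import pandas as pd
import pytest

from aphidfx import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def default_dataset():
    """One medium synthetic dataset shared by read-only tests."""
    return simulate_all(SimulationConfig(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def nb_counts(rng, n_genes, libsizes, phi, log2_weight_range=(-4.0, 4.0),
              multipliers=None):
    """Plain NB count matrix helper for focused statistical tests."""
    w = 2.0 ** rng.uniform(*log2_weight_range, size=n_genes)
    rel = w / w.sum()
    mean = rel[:, None] * np.asarray(libsizes, dtype=float)[None, :]
    if multipliers is not None:
        mean = mean * multipliers
    if phi == 0:
        y = rng.poisson(mean)
    else:
        size = 1.0 / phi
        y = rng.negative_binomial(size, size / (size + mean))
    return pd.DataFrame(y, columns=[f"s{i}" for i in range(len(libsizes))])
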