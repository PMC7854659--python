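import numpy as np
import pandas as pd
import pytest

from coexnet import preprocess, simulate


@pytest.fixture(scope="session")
def small_config():
    """A compact study: 150 genes, 3 tissues, 7+7 fetuses, 3 modules."""
    return simulate.SimConfig(
        n_genes=150, n_ts_per_tissue=8, n_de=10, n_modules=3, module_size=8,
        coupling_con=(0.9, 0.8, 0.9), coupling_res=(0.9, -0.8, 0.0), seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_normalized(small_dataset):
    counts, metadata, _ = small_dataset
    nm = preprocess.normalize_counts(counts, metadata, strategy="pooled")["pooled"]
    return nm.data, metadata


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_correlation(n_genes: int, n_samples: int, seed: int) -> np.ndarray:
    """A proper (positive semidefinite) random correlation matrix."""
    r = np.random.default_rng(seed)
    x = r.standard_normal((n_genes, n_samples))
    return np.corrcoef(x)
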