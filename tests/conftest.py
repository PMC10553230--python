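import numpy as np
import pytest

from vaebench import generate_dataset, zscore_genes


@pytest.fixture(scope="session")
def small_dataset():
    """120 samples x 40 genes, 3 clusters — fast shared fixture."""
    data, truth = generate_dataset(n_samples=120, n_genes=40, n_clusters=3,
                                   cluster_separation=10.0, noise_sd=1.0, seed=7)
    return zscore_genes(data), truth


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free dataset: deterministic links, exact factor structure."""
    data, truth = generate_dataset(n_samples=200, n_genes=30, n_clusters=4,
                                   cluster_separation=50.0, noise_sd=0.0, seed=11)
    return data, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
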