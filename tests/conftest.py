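import numpy as np
import pytest

from eegsmote import ClusterConfig, LabeledDataset, make_clusters


@pytest.fixture
def toy_2d():
    """Two well-separated 2-D clusters, 30 majority + 10 minority."""
    ds, _ = make_clusters(ClusterConfig(n_major=30, n_minor=10,
                                        separation=6.0, seed=42))
    return ds


@pytest.fixture
def noisy_clusters():
    """Standard planted-noise fixture: 300 vs 10 with 20% planted noise."""
    return make_clusters(ClusterConfig(n_major=300, n_minor=10,
                                       noise_frac=0.2, separation=4.0,
                                       seed=1))


def random_imbalanced(rng, n_maj=None, n_min=None, d=None):
    """A random imbalanced dataset (helper for contract sweeps)."""
    n_maj = n_maj or int(rng.integers(30, 80))
    n_min = n_min or int(rng.integers(4, max(5, n_maj // 3)))
    d = d or int(rng.integers(2, 6))
    X = np.vstack([rng.normal(0, 1, (n_maj, d)),
                   rng.normal(2.0, 1, (n_min, d))])
    y = np.concatenate([np.zeros(n_maj, int), np.ones(n_min, int)])
    return LabeledDataset(X, y)
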