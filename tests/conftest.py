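import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import topohet as th

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


def make_expr(values, gene_ids=None, sample_ids=None) -> th.ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or tuple(f"G{i}" for i in range(values.shape[0]))
    sample_ids = sample_ids or tuple(f"S{j}" for j in range(values.shape[1]))
    return th.ExpressionMatrix(tuple(gene_ids), tuple(sample_ids), values)


def random_point_cloud_matrix(rng, n, dim=3) -> np.ndarray:
    """Euclidean distance matrix of a random point cloud (a true metric)."""
    from scipy.spatial.distance import pdist, squareform
    return squareform(pdist(rng.normal(size=(n, dim))))


def random_symmetric_matrix(rng, n, low=0.05, high=2.0) -> np.ndarray:
    """Random symmetric dissimilarity (not necessarily a metric)."""
    m = rng.uniform(low, high, size=(n, n))
    d = np.triu(m, 1)
    return d + d.T


@pytest.fixture(scope="session")
def null_dataset() -> th.SyntheticDataset:
    """Exchangeable two-group dataset (heterogeneity = 1)."""
    return th.generate(th.SyntheticConfig(n_genes=60, n_per_group=15, seed=11))


@pytest.fixture(scope="session")
def heterogeneous_dataset() -> th.SyntheticDataset:
    """Case group with threefold residual dispersion."""
    return th.generate(th.SyntheticConfig(n_genes=60, n_per_group=15,
                                          heterogeneity=3.0, seed=11))


@pytest.fixture(scope="session")
def restricted_dataset() -> th.SyntheticDataset:
    """Heterogeneity confined to a 20% affected gene subset."""
    return th.generate(th.SyntheticConfig(n_genes=150, n_per_group=15,
                                          heterogeneity=3.0,
                                          affected_fraction=0.2,
                                          restricted=True, seed=11))
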