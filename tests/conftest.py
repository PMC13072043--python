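import numpy as np
import pytest

from mrigcn.embeddings import BackboneContract, EmbeddingTable
from mrigcn.graph import GraphConfig, build_graph
from mrigcn.synthetic import SyntheticConfig, make_split, sample_embeddings


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def mean_backbone():
    """Deterministic fixture backbone: per-channel pixel means (d=3)."""
    return BackboneContract(embed=lambda batch: batch.mean(axis=(1, 2)), output_dim=3)


@pytest.fixture
def projection_backbone():
    """Fixed random projection of flattened pixels to 16 dims."""
    proj_rng = np.random.default_rng(7)
    P = proj_rng.standard_normal((299 * 299 * 3, 16)) / np.sqrt(299 * 299 * 3)
    return BackboneContract(
        embed=lambda batch: batch.reshape(batch.shape[0], -1) @ P, output_dim=16
    )


@pytest.fixture
def small_table():
    cfg = SyntheticConfig(
        n_per_class=(12, 12, 12, 12), dim=16, noise_sd=0.05, seed=5
    )
    return sample_embeddings(cfg)


@pytest.fixture
def small_graph(small_table):
    masks = make_split(small_table.labels, 0.25, 0.2, seed=5)
    g = build_graph(
        small_table.vectors,
        small_table.labels,
        *masks,
        GraphConfig(k=4, tau=0.5, seed=5),
    )
    return g, small_table, masks


def dense_normalized_adjacency(pairs, n):
    """Independent dense oracle for D^(-1/2) A D^(-1/2)."""
    A = np.zeros((n, n))
    for i, j in pairs:
        A[i, j] = 1.0
    d = A.sum(axis=1)
    Dinv = np.diag(1.0 / np.sqrt(d))
    return Dinv @ A @ Dinv
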