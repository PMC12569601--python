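import numpy as np
import pytest

from gtnorm import CountMatrix, CountProfile
import scipy.sparse as sp


def make_profile(counts, ids=None):
    counts = np.asarray(counts, dtype=np.int64)
    if ids is None:
        ids = np.array([f"g{i}" for i in range(len(counts))], dtype=object)
    return CountProfile(gene_ids=ids, counts=counts)


def random_profile(rng, n_genes_max=50, total_max=500):
    """Small random cell profile with at least one observed gene."""
    n = rng.integers(2, n_genes_max + 1)
    total = int(rng.integers(1, total_max + 1))
    probs = rng.dirichlet(np.full(n, rng.uniform(0.05, 1.0)))
    counts = rng.multinomial(total, probs)
    if counts.sum() == 0:  # cannot happen, but keep the invariant obvious
        counts[0] = 1
    return make_profile(counts)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_matrix(rng):
    """Random sparse 30 genes x 12 cells count matrix, no empty cells."""
    dense = rng.negative_binomial(1, 0.3, size=(30, 12))
    dense[:, 0] = 0
    dense[0, 0] = 5  # keep every column nonempty
    genes = np.array([f"ENSG{i:05d}" for i in range(30)], dtype=object)
    cells = np.array([f"BC{j:04d}" for j in range(12)], dtype=object)
    return CountMatrix(gene_ids=genes, barcodes=cells, matrix=sp.csc_matrix(dense))
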