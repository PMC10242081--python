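import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from endoase import AlleleCountMatrix, SimConfig, simulate_trio
from endoase.qc import filter_cells_genes, normalize_log_cpm


@pytest.fixture(scope="session")
def default_trio():
    """Default-condition trio (1,000 nuclei/sample, 10,000 genes)."""
    return simulate_trio(SimConfig(seed=7))


@pytest.fixture(scope="session")
def small_trio():
    """Fast trio for unit tests; same structure, reduced scale."""
    cfg = SimConfig(
        n_nuclei_per_sample=150, n_genes=1500, n_clusters=3,
        n_meg=30, n_peg=30, n_pattern_genes_per_class=15,
        n_mode_genes_per_class=15, seed=3,
    )
    return simulate_trio(cfg)


@pytest.fixture(scope="session")
def clustered_hybrid(default_trio):
    """Filtered + normalized hybrid sample with ground-truth labels."""
    hyb = normalize_log_cpm(filter_cells_genes(default_trio.matrices["hybrid"]))
    truth = np.array(
        [default_trio.truth.cluster_of_nucleus[b] for b in hyb.barcodes]
    )
    return hyb, truth


def make_acm(counts, maternal=None, paternal=None, genes=None, barcodes=None):
    counts = np.asarray(counts)
    n, g = counts.shape
    return AlleleCountMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=np.array(genes if genes is not None
                          else [f"g{j}" for j in range(g)], dtype=object),
        barcodes=np.array(barcodes if barcodes is not None
                          else [f"n{i}" for i in range(n)], dtype=object),
        maternal=None if maternal is None else sp.csr_matrix(np.asarray(maternal)),
        paternal=None if paternal is None else sp.csr_matrix(np.asarray(paternal)),
    )
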