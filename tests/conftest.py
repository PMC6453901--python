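import numpy as np
import pytest
from scipy import sparse

import planmat as pm
from planmat import io as pio
from planmat.types import ExpressionMatrix


@pytest.fixture(scope="session")
def catalog():
    return pio.load_domain_catalog()


@pytest.fixture(scope="session")
def default_bundle():
    """Default synthetic evidence bundle (20 contigs per class, seed 1)."""
    bundle, human_map, truth = pm.gen_evidence_bundle(20, seed=1)
    return bundle, pm.HumanMatrisomeMap(human_map), truth


@pytest.fixture(scope="session")
def sim_data():
    """One simulated atlas shared across expression tests (3000 cells,
    muscle 10%, matrisome fold-change 8)."""
    cfg = pm.SimConfig(n_cells=3000, seed=7)
    matrix, annot, sets = pm.gen_sc_counts(cfg)
    pm.normalize_cp10k(matrix)
    return matrix, annot, sets


def small_matrix(n_genes=48, n_cells=30, seed=0, density=0.4):
    """Small random log-normalized matrix for unit tests."""
    rng = np.random.default_rng(seed)
    counts = (rng.random((n_genes, n_cells)) < density) * rng.integers(
        1, 20, size=(n_genes, n_cells)
    )
    m = ExpressionMatrix(
        counts=sparse.csr_matrix(counts),
        gene_ids=[f"g{i:03d}" for i in range(n_genes)],
        cell_ids=[f"c{i:03d}" for i in range(n_cells)],
    )
    return pm.normalize_cp10k(m)
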