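import numpy as np
import pytest

from sneqtl import cis, pseudobulk
from sneqtl.simulate import (
    SimConfig,
    make_ground_truth,
    simulate_genotypes,
    simulate_nuclei,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest five-cell-type cohort with planted effect patterns,
    shared across tests that only read from it."""
    cfg = SimConfig(n_donors=150, n_genes=30, n_variants_per_gene=6,
                    n_cell_types=5, trans_chains=2, seed=7)
    geno = simulate_genotypes(cfg)
    truth = make_ground_truth(cfg)
    adata = simulate_nuclei(cfg, geno, truth)
    return cfg, geno, truth, adata


@pytest.fixture(scope="session")
def small_pseudobulk(small_cohort):
    _, _, _, adata = small_cohort
    pb = pseudobulk.aggregate(adata, level="subclass")
    return pseudobulk.normalize(pb, min_donors=20)


@pytest.fixture(scope="session")
def small_cis_table(small_cohort, small_pseudobulk):
    _, geno, _, _ = small_cohort
    return cis.map_cis(small_pseudobulk, geno, n_min=30)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
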