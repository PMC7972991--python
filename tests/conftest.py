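import numpy as np
import pytest

from mmntwas import genotypes, simulate
from mmntwas.simulate import SimConfig


@pytest.fixture(scope="session")
def small_study():
    """One small cohort: genotypes, weight models, true GReX, phenotypes."""
    cfg = SimConfig(n_individuals=500, n_snps=200, n_genes=40, snps_per_gene=5, seed=42)
    geno = simulate.simulate_genotypes(cfg)
    models, grex_true = simulate.simulate_weight_models(geno, cfg)
    pheno = simulate.simulate_phenotype(grex_true, cfg)
    return {"config": cfg, "genotypes": geno, "models": models,
            "grex_true": grex_true, "phenotypes": pheno}


@pytest.fixture(scope="session")
def small_grm():
    """GRM over 500 individuals from 1000 LD-free SNPs."""
    cfg = SimConfig(n_individuals=500, n_snps=1000, ld_block_size=1,
                    n_genes=1, snps_per_gene=1, seed=7)
    geno = simulate.simulate_genotypes(cfg)
    return genotypes.compute_grm(geno)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
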