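import numpy as np
import pytest

from bovqtl.simdata import (
    SimConfig,
    SweepConfig,
    simulate_expression,
    simulate_gene_models,
    simulate_haplotypes,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A compact cohort reused across read-only unit tests."""
    return SimConfig(
        seed=11,
        n_individuals=200,
        n_chromosomes=2,
        variants_per_chrom=1000,
        chrom_length_bp=10_000_000,
        n_genes=100,
    )


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return simulate_haplotypes(small_cfg)


@pytest.fixture(scope="session")
def poly_panel(small_panel):
    """The small panel restricted to polymorphic variants (GRM-safe)."""
    p = small_panel.allele_freq()
    return small_panel.subset(variant_mask=(p > 0) & (p < 1))


@pytest.fixture(scope="session")
def small_pheno(small_cfg, small_panel):
    pheno, truth, gvals = simulate_phenotypes(small_panel, small_cfg)
    return pheno, truth, gvals


@pytest.fixture(scope="session")
def small_genes(small_cfg):
    return simulate_gene_models(small_cfg)


@pytest.fixture(scope="session")
def small_expression(small_cfg, small_panel, small_genes):
    return simulate_expression(small_panel, small_genes, small_cfg)


@pytest.fixture(scope="session")
def pheno_covariates(small_pheno):
    import pandas as pd

    pheno = small_pheno[0]
    farm = pd.get_dummies(pheno["farm"], drop_first=True, dtype=float)
    return np.column_stack([farm.to_numpy(), pheno["sex"].to_numpy(dtype=float)])
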