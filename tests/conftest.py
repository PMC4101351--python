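import numpy as np
import pytest

from igscan.io import GenotypeMatrix
from igscan.simulate import builtin_model, simulate_case_control


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_null_matrix(rng):
    """20 unassociated SNPs x 60 samples, some missing calls."""
    geno = rng.binomial(2, 0.3, size=(60, 20)).astype(np.int8)
    miss = rng.random(geno.shape) < 0.03
    geno[miss] = -1
    pheno = np.repeat([1, 0], 30).astype(np.int8)
    return GenotypeMatrix(geno, pheno)


@pytest.fixture
def planted_pair_matrix(rng):
    """Phenotype deterministically indicates one joint-genotype cell of SNPs (3, 7)."""
    geno = rng.binomial(2, 0.4, size=(120, 10)).astype(np.int8)
    pheno = ((geno[:, 3] == 1) & (geno[:, 7] == 1)).astype(np.int8)
    if pheno.sum() in (0, len(pheno)):  # pragma: no cover - seed keeps both classes
        pheno[0] = 1 - pheno[0]
    return GenotypeMatrix(geno, pheno)


@pytest.fixture(scope="session")
def multiplicative_dataset():
    """Marginal-effect model with noise SNPs, moderate size."""
    return simulate_case_control(
        builtin_model("multiplicative"), 150, 150, m_noise_snps=28, seed=99
    )
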