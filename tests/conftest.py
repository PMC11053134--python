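import numpy as np
import pandas as pd
import pytest

from ckdclust import synthetic
from ckdclust.pipeline import matrix_from_truth


@pytest.fixture(scope="session")
def truth_k4():
    """Planted K=4 ground truth, moderately sparse."""
    return synthetic.generate_truth(K=4, n_traits=60, n_variants=120, sparsity=0.3, seed=1)


@pytest.fixture(scope="session")
def matrix_k4(truth_k4):
    """Association matrix built through the full record path."""
    X, log = matrix_from_truth(truth_k4, noise_sd=0.1, seed=2)
    return X


@pytest.fixture(scope="session")
def truth_k3():
    return synthetic.generate_truth(K=3, n_traits=30, n_variants=60, sparsity=0.0, seed=11)


@pytest.fixture(scope="session")
def genotypes_two_groups():
    return synthetic.generate_genotypes(
        600, 300, [("EUR", 0.5, (0.05, 0.2)), ("AFR", 0.5, (0.3, 0.5))], seed=3
    )


@pytest.fixture(scope="session")
def scored_cohort(truth_k3):
    """Genotypes + phenotypes + standardized cluster scores for K=3."""
    from ckdclust import scores

    geno = synthetic.generate_genotypes(2000, truth_k3.n_variants, seed=2)
    pheno = synthetic.generate_phenotypes(
        geno.dosages, truth_k3, h2=0.3, prevalence=0.15, seed=3
    )
    H = pd.DataFrame(
        truth_k3.H_true,
        index=[f"C{k}" for k in range(truth_k3.K_true)],
        columns=truth_k3.variant_labels,
    )
    raw, _ = scores.compute_cpgs(geno.dosages, H)
    z = scores.standardize_cpgs(raw)
    return geno, pheno, z
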