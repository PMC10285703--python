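"""Shared fixtures: small simulated cohorts generated once per session."""
import numpy as np
import pytest

from bchfkit.genotypes import compute_grm, maf_filter, recode_genotypes
from bchfkit.simulate import SimulationConfig, simulate_breed_panel, simulate_population


@pytest.fixture(scope="session")
def small_panel():
    """4-breed reference panel, 3000 loci, moderate divergence."""
    return simulate_breed_panel(4, 3000, 0.15, seed=11)


@pytest.fixture(scope="session")
def family_cohort():
    """Half-sib structured cohort with a heritable liability (n=400)."""
    config = SimulationConfig(
        n_individuals=400, n_loci=2000, n_sires=20, seed=42,
        genetic_covariance=0.554, residual_covariance=1.0,
    )
    gm, pheno, truth = simulate_population(config)
    grm = compute_grm(recode_genotypes(maf_filter(gm, 0.01)))
    return gm, pheno, truth, grm


@pytest.fixture(scope="session")
def unrelated_cohort():
    """Unstructured cohort (Dirichlet admixture, linkage equilibrium)."""
    config = SimulationConfig(n_individuals=300, n_loci=2500, seed=7)
    gm, pheno, truth = simulate_population(config)
    grm = compute_grm(recode_genotypes(maf_filter(gm, 0.01)))
    return gm, pheno, truth, grm


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
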