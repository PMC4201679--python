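"""Shared fixtures: one study-scale population and one small population.

The study population follows the reference design (20 F0, 51 F1, 511 F2
in 8 paternal half-sib families) with a 2,000-SNP panel on 10
chromosomes; the heavier cross-validation fixtures are session-scoped so
the MCMC work runs once.
"""

import numpy as np
import pytest

import gpcross as g
from gpcross.qc import impute_missing
from gpcross.wgr import MCMCConfig

POP_SEED = 101
STUDY_SEED = 202


@pytest.fixture(scope="session")
def ref_population():
    """Study-design population: 582 genotyped birds, 8 half-sib families."""
    return g.simulate_population(n_snps=2000, seed=POP_SEED)


@pytest.fixture(scope="session")
def ref_geno(ref_population):
    return impute_missing(ref_population.genotypes)


@pytest.fixture(scope="session")
def study_report(ref_population):
    """Full cross-validation study: all five traits, both scenarios."""
    return g.run_study(
        ref_population,
        mcmc=MCMCConfig.desk(),
        seed=STUDY_SEED,
        include_full_data=True,
    )


@pytest.fixture(scope="session")
def small_population():
    """Desk-scale population for cheap structural checks."""
    return g.simulate_population(
        n_snps=400, n_f2=160, n_f1=24, n_sires_f1=8, seed=POP_SEED
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
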