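import logging

import numpy as np
import pytest

from sumtwas import (
    ArchitectureConfig,
    LocusConfig,
    simulate_genotypes,
    simulate_study,
)

# the tetrachoric-bound warning is expected at high ld_rho with extreme MAF
# pairs and would otherwise flood the test log
logging.getLogger("sumtwas.simulate").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_panel():
    """n=2000 individuals, 12 SNPs, moderate LD — shared read-only panel."""
    cfg = LocusConfig(n_snps=12, maf_range=(0.1, 0.5), ld_rho=0.4, seed=101)
    return simulate_genotypes(cfg, 2000)


@pytest.fixture(scope="session")
def alt_study():
    """One mediated-scenario study (E) with a single tissue, n_gwas=5000."""
    locus = LocusConfig(n_snps=15, maf_range=(0.1, 0.5), ld_rho=0.4, seed=202)
    arch = ArchitectureConfig(
        n_causal_eqtl=3, cis_h2=0.5, scenario="E", trait_h2_via_expression=0.05
    )
    return simulate_study(locus, arch, n_ref=500, n_gwas=5000)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
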