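import numpy as np
import pandas as pd
import pytest

from circartp.simulate import (
    PanelSpec,
    simulate_covariates,
    simulate_genotypes,
    simulate_outcome,
)


@pytest.fixture(scope="session")
def null_cohort():
    """Small null dataset: 3 genes (3+2+1 SNPs), 400 individuals, no effects."""
    panel = PanelSpec(
        genes=(("GENEA", 3), ("GENEB", 2), ("GENEC", 1)), ld_rho=0.3, seed=11
    )
    genotypes = simulate_genotypes(panel, 400)
    covariates = simulate_covariates(400, seed=12)
    cohort = simulate_outcome(genotypes, covariates, seed=13)
    return genotypes, cohort


@pytest.fixture(scope="session")
def status_only_cohort():
    """Tiny genotypes + a bare status table (no covariates needed)."""
    panel = PanelSpec(genes=(("G1", 3),), ld_rho=0.3, seed=5, maf_range=(0.2, 0.4))
    genotypes = simulate_genotypes(panel, 120)
    rng = np.random.default_rng(6)
    cohort = pd.DataFrame(
        {"status": rng.integers(0, 2, size=120)}, index=genotypes.dosages.index
    )
    return genotypes, cohort
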