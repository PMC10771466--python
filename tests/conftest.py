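import numpy as np
import pandas as pd
import pytest

from cmqtl.config import SimulationConfig
from cmqtl.simulate import simulate_genotypes, simulate_profiles


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_donors=60,
        n_plates=3,
        wells_per_donor=4,
        cells_per_well_mean=30,
        n_traits=10,
        n_common_variants=50,
        n_genes=20,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """(genotypes, truth, single-cell table) at smoke-test scale."""
    geno, truth = simulate_genotypes(small_config)
    cells, truth = simulate_profiles(small_config, geno, truth)
    return geno, truth, cells


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20250920)


@pytest.fixture(scope="session")
def donor_frame():
    """Donor-indexed metadata/covariate inputs shared by association tests."""
    r = np.random.default_rng(7)
    n = 300
    donors = pd.Index([f"D{i:03d}" for i in range(n)], name="donor_id")
    meta = pd.DataFrame(
        {
            "age": r.integers(20, 70, n),
            "sex": r.choice(["male", "female"], n),
        },
        index=donors,
    )
    pcs = pd.DataFrame(
        r.normal(size=(n, 4)), index=donors, columns=["PC1", "PC2", "PC3", "PC4"]
    )
    plates = pd.Series(r.choice(["P1", "P2", "P3"], n), index=donors)
    return meta, pcs, plates
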