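import numpy as np
import pandas as pd
import pytest

from pofokit.maps import GeneticMap
from pofokit.simkit import SimConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_map():
    """Two small chromosomes with hand-checkable piecewise-linear maps."""
    return GeneticMap(
        {
            "1": pd.DataFrame(
                {
                    "pos": [0, 500, 1000],
                    "cm_female": [0.0, 2.0, 6.0],
                    "cm_male": [0.0, 1.0, 2.0],
                }
            ),
            "2": pd.DataFrame(
                {"pos": [0, 1000], "cm_female": [0.0, 4.0], "cm_male": [0.0, 4.0]}
            ),
        }
    )


@pytest.fixture(scope="session")
def trio_cohort():
    """Error-free trio-only cohort used by kinship / phasing oracles."""
    cfg = SimConfig(
        n_families=30,
        family_menu={"trio": 1.0},
        chromosomes=["21", "22"],
        variants_per_cm=12.0,
        genotype_error_rate=0.0,
        switch_error_rate=0.0,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def mixed_cohort():
    """Small mixed-relationship cohort (clean data) shared across tests."""
    # relationship classification needs genome-scale kinship: short genomes
    # inflate the variance of true IBD fractions between relatives
    cfg = SimConfig(
        n_families=40,
        family_menu={"trio": 0.2, "sib": 0.2, "deg2": 0.3, "deg3": 0.15,
                     "deg4": 0.15},
        variants_per_cm=10.0,
        genotype_error_rate=0.0,
        switch_error_rate=0.0,
        seed=5,
    )
    return simulate_cohort(cfg)
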