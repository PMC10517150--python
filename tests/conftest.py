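import numpy as np
import pytest

from mphl_exwas.config import SimulationConfig
from mphl_exwas.simulate import simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic cohort shared across tests."""
    config = SimulationConfig(
        n_samples=400,
        n_genes=30,
        variants_per_gene=4.0,
        causal_genes={"G0002": 0.6},
        misreport_rate=0.05,
        kinship_rate=0.02,
        genotype_missing_rate=0.01,
        seed=20240915,
    )
    return config, simulate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
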