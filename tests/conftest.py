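import numpy as np
import pytest

from rarecollapse import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with planted structure, shared across read-only tests."""
    cfg = SimulationConfig(
        n_cases=60,
        n_controls=240,
        n_genes=40,
        background_carrier_prob=0.02,
        risk_genes={"G00001": 0.3},
        n_panel_snps=1500,
        imbalanced_site_fraction=0.15,
        related_pairs=[("duplicate", 1), ("parent_offspring", 2)],
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
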