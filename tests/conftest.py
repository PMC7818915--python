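import numpy as np
import pytest

import ftqc


@pytest.fixture(scope="session")
def small_cohort():
    """A small degraded cohort shared across read-only tests."""
    cfg = ftqc.SyntheticConfig(
        n_individuals=8,
        replicates_per_individual=2,
        n_genes=600,
        depth=15_000,
        noise_per_cycle=0.04,
        seed=7,
    )
    counts, metadata, truth = ftqc.generate_cohort(cfg)
    return cfg, counts, metadata, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
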