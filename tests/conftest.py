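import numpy as np
import pytest

from circadhs import simdata

TIMES = np.array([2.0, 6.0, 10.0, 14.0, 18.0, 22.0, 26.0])


@pytest.fixture(scope="session")
def tiny_sim():
    """Small but complete synthetic study shared across read-only tests."""
    cfg = simdata.SimConfig(
        genome_length=600_000, n_chromosomes=1, n_genes=12, n_dhs=36,
        distal_max_bp=20_000, seq_depth=200.0, seed=42,
    )
    return simdata.simulate_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
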