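import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from dyadsim import SimulationConfig, SNPPanel, simulate_trios

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_panel(freqs, weights=None, prefix="snp"):
    """Hand-built panel with unambiguous A/G alleles."""
    m = len(freqs)
    if weights is None:
        weights = np.ones(m)
    return SNPPanel(pd.DataFrame({
        "snp_id": [f"{prefix}_{j + 1:03d}" for j in range(m)],
        "effect_allele": ["A"] * m,
        "other_allele": ["G"] * m,
        "weight": np.asarray(weights, dtype=float),
        "freq": np.asarray(freqs, dtype=float),
    }))


@pytest.fixture
def small_panel():
    return make_panel([0.2, 0.5, 0.7], weights=[0.2, 0.5, -0.3])


@pytest.fixture
def tiny_cohort():
    cfg = SimulationConfig(n_trios=60, n_snps=20, seed=11)
    panel, cohort = simulate_trios(cfg, cfg.rng())
    return cfg, panel, cohort
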