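import numpy as np
import pytest

from acadscreen import SimulationConfig, default_panel, generate_cohort


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded 500-newborn cohort with a handful of forced cases."""
    cfg = SimulationConfig(
        n=500,
        prevalence={"SCAD": 0.01, "MCAD": 0.005, "VLCAD": 0.005},
        seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
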