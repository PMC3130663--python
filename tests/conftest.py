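import numpy as np
import pytest

from mrresponse import GeneratorConfig, VIFParams, simulate_cohort


@pytest.fixture(scope="session")
def default_vif() -> VIFParams:
    return VIFParams()


@pytest.fixture(scope="session")
def dce_times() -> np.ndarray:
    """The acquisition grid: 12 s frames over 20 minutes from injection."""
    return np.arange(0.0, 1200.0 + 1e-9, 12.0)


@pytest.fixture(scope="session")
def small_cohort():
    """A study-sized cohort: 4 groups of 8 animals."""
    return simulate_cohort(GeneratorConfig(n_per_group=8, seed=42))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
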