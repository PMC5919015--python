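import numpy as np
import pytest

from mirharmonic import HarmonicParams, SimulationConfig, simulate


@pytest.fixture(scope="session")
def order1_truth() -> HarmonicParams:
    """A realistic annual-cycle truth: mean ~58 %, strong seasonal swing."""
    return HarmonicParams(1, 58.0, -22.0, -29.0, 12.0)


@pytest.fixture(scope="session")
def order2_truth() -> HarmonicParams:
    return HarmonicParams(2, 58.0, -22.0, -29.0, 12.0, beta3=-8.0, beta4=-5.0)


@pytest.fixture(scope="session")
def clean_dataset(order1_truth):
    """300 records (25/month) with 5 % multiplicative noise, fixed seed."""
    return simulate(
        SimulationConfig(true_params=order1_truth, n_per_month=25, sigma_log=0.05, seed=42)
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
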