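import numpy as np
import pytest
from hypothesis import settings

from uvchron import (
    IrradiationSettings,
    RandomerDesign,
    make_synthetic_context_rates,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_table():
    """Deterministic synthetic context-rate table (no jitter)."""
    return make_synthetic_context_rates()


@pytest.fixture(scope="session")
def jittered_table():
    """Synthetic table with 30% relative rate jitter, fixed seed."""
    from uvchron import SyntheticRateModel

    return make_synthetic_context_rates(
        SyntheticRateModel(noise_sd=0.3), np.random.default_rng(99)
    )


@pytest.fixture(scope="session")
def small_settings():
    """Reduced pool for fast Monte Carlo tests."""
    return IrradiationSettings(dose=2.0, seed=11, n_strands=2000, strand_length=150)


@pytest.fixture(scope="session")
def tiny_design():
    """4-base random core: 256 randomers, doses up to 2 PpB."""
    return RandomerDesign(random_length=4, doses=tuple(0.25 * k for k in range(9)))
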