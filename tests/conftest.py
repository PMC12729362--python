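import numpy as np
import pytest

from invadenet.phantom import PhantomConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """60-patient noise-on cohort used by several suites."""
    return simulate_cohort(PhantomConfig(n_patients=60, image_size=64, seed=11))


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free cohort: tumor curves are exactly the class kinetics."""
    cfg = PhantomConfig(
        n_patients=24, image_size=64, rician_sigma=0.0, gaussian_sigma=0.0,
        missing_phase_prob=0.0, washin_slope_sd=0.0, seed=5,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
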