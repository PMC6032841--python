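import pytest

from pinkfoot.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small but realistic simulated dataset shared across tests."""
    cfg = SimConfig(n_years=10, ringing_per_year=40, seed=42)
    birds, resightings, covariates, truth = simulate_dataset(cfg)
    return cfg, birds, resightings, covariates, truth


@pytest.fixture(scope="session")
def perfect_dataset():
    """Perfect-detection dataset: every latent region is sighted."""
    cfg = SimConfig(n_years=8, ringing_per_year=30, seed=7, perfect_detection=True)
    birds, resightings, covariates, truth = simulate_dataset(cfg)
    return cfg, birds, resightings, covariates, truth
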