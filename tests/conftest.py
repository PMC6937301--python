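import pytest

from embryorigin.synthetic_data import SimulationConfig, simulate_dataset


def noise_free_config(**overrides) -> SimulationConfig:
    """A configuration with every stochastic margin removed: Poisson counts
    at the expressed level, structural zeros for background, no array or
    qPCR noise.  Downstream stages must recover the planted truth exactly."""
    defaults = dict(
        seed=11,
        n_genes=2000,
        nb_dispersion=0.0,
        background_mean=0.0,
        array_background_mean=0.0,
        qpcr_noise_sd=0.0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def noise_free_dataset():
    return simulate_dataset(noise_free_config())


@pytest.fixture(scope="session")
def stochastic_dataset():
    """Default study conditions: NB dispersion 0.2, background mean 0.5."""
    return simulate_dataset(SimulationConfig(seed=23, n_genes=3000))
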