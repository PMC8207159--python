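import numpy as np
import pytest

from extvortex.lpd import PopulationTimeSeries
from extvortex.sampler import SamplerConfig
from extvortex.simulate import VortexGeneratorConfig, generate_study


def make_series(values, start_year=2000, series_id="s1", species="Testus exemplaris",
                **kwargs):
    """Series from a value list; None entries become missing years."""
    obs = {
        start_year + i: v for i, v in enumerate(values) if v is not None
    }
    return PopulationTimeSeries(
        series_id=series_id, species_binomial=species, observations=obs, **kwargs
    )


@pytest.fixture(scope="session")
def accepted_series():
    """A 12-year decline with ten nonzero observations and two terminal zeros."""
    return make_series([100, 80, 60, 50, 40, 30, 20, 10, 5, 3, 0, 0])


@pytest.fixture(scope="session")
def small_study():
    """A small default-dynamics synthetic study shared across tests."""
    return generate_study(VortexGeneratorConfig(n_species=8, n_populations=10, seed=42))


@pytest.fixture(scope="session")
def fast_sampler():
    """Short sampler settings for smoke-level model fits."""
    return SamplerConfig(chains=4, iterations=700, warmup=300, seed=123)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
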