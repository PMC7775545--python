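import numpy as np
import pytest

from phenobridge.phenology import CardinalConstants, EnvironmentSeries


@pytest.fixture(scope="session")
def cardinals():
    return CardinalConstants()


def constant_env(t=30.0, p=10.0, n=250, env_id="const", lat=36.0):
    return EnvironmentSeries(env_id=env_id, latitude=lat, longitude=135.0,
                             sowing_date=None,
                             temperatures=np.full(n, float(t)),
                             photoperiods=np.full(n, float(p)))


@pytest.fixture
def make_constant_env():
    return constant_env


@pytest.fixture(scope="session")
def small_study():
    """Small synthetic study shared by pipeline-level tests."""
    from phenobridge.synth import generate_study

    return generate_study(n_genotypes=8, n_sites=3, n_years=2,
                          noise_sd=1.0, seed=42)
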