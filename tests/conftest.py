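import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vinegc
from vinegc import io as vio

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def constants():
    return vinegc.DEFAULT_CONSTANTS


@pytest.fixture(scope="session")
def site():
    """The study site: 220 m elevation, z_m 3 m, h 1.7 m, LAI 1.96."""
    return vinegc.STUDY_SITE


@pytest.fixture
def rng():
    return np.random.default_rng(20240206)


def make_campaign(seed=7, n_days=1, **scenario_kwargs):
    params = vinegc.ScenarioParams(seed=seed, **scenario_kwargs)
    return vinegc.generate_campaign(params, n_days=n_days)


def bundle_of(campaign):
    return vio.RawDatasetBundle(
        meteo=campaign.meteo, leaf=campaign.leaf, flux=campaign.flux, site=campaign.site
    )


@pytest.fixture
def noiseless_campaign():
    return make_campaign(seed=7, n_days=1)
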