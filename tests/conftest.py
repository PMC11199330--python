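import dataclasses

import numpy as np
import pytest

import fjordpp as fp


@pytest.fixture(scope="session")
def campaign_scenarios():
    """The default 2-fjord x 3-zone campaign at study conditions."""
    return fp.default_campaign()


@pytest.fixture(scope="session")
def campaign():
    """A full synthetic campaign (30 casts/zone, 10% noise), seeded."""
    casts, truths = fp.generate_campaign(fp.default_campaign(), seed=20080715)
    return casts, truths


@pytest.fixture()
def noiseless_glacier_scenario():
    """Hornsund Glacier stratum with all stochastic terms switched off."""
    sc = fp.default_campaign()[3]
    assert (sc.fjord, sc.zone) == ("Hornsund", "Glacier")
    return dataclasses.replace(sc, noise_cv=0.0, biomass_cv=0.0,
                               surface_salinity_sd=0.0, surface_temp_sd=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
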