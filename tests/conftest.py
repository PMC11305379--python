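"""Shared fixtures: a small synthetic world and a fitted intake model.

The small world (2 regions x 3 countries x 4 years) is sized so that a full
MCMC fit takes a few seconds; fixtures are session-scoped and reused across
test modules.
"""
import logging
import warnings

import numpy as np
import pytest

import dietstrata as ds

warnings.filterwarnings("ignore", category=FutureWarning)
logging.getLogger("dietstrata").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_world():
    cfg = ds.WorldConfig(n_regions=2, countries_per_region=3,
                         years=(1990, 2000, 2010, 2018), seed=1)
    world = ds.generate_world(cfg)
    pops = ds.generate_populations(world)
    surveys = ds.harmonize_surveys(ds.simulate_surveys(world, populations=pops))
    covariates = ds.generate_covariates(world)
    return {"world": world, "pops": pops, "surveys": surveys,
            "covariates": covariates}


@pytest.fixture(scope="session")
def small_fit(small_world):
    spec = ds.ModelSpec(chains=2, warmup=200, draws=200, seed=5)
    post = ds.fit_intake_model(small_world["surveys"], small_world["covariates"],
                               spec, small_world["pops"])
    return post


@pytest.fixture()
def rng():
    return np.random.default_rng(20240807)
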