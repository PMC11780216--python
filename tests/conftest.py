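"""Shared fixtures: small seeded synthetic datasets and one reusable fit.

The session-scoped census fit keeps the slower model-dependent tests cheap:
they all interrogate the same moderate-size posterior rather than refitting.
"""

import warnings

import numpy as np
import pytest

from seabird_cascade import (
    CensusSimParams,
    HurdleSpec,
    PreyFieldSimParams,
    ReefSimParams,
    fit_hurdle_lognormal,
    generate_census,
    generate_prey_field,
    generate_reef_survey,
    prepare_design,
)

# silence arviz's refactor FutureWarning globally for the suite
warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def census_params():
    return CensusSimParams(n_islands=60, seed=11)


@pytest.fixture(scope="session")
def census(census_params):
    return generate_census(census_params)


@pytest.fixture(scope="session")
def fitted(census, census_params):
    """Design + posterior of the hurdle model on the session census."""
    spec = HurdleSpec(chains=4, iterations=1200, warmup=400, seed=42)
    design = prepare_design(census, spec)
    posterior = fit_hurdle_lognormal(design, spec)
    return design, posterior


@pytest.fixture()
def prey_field():
    return generate_prey_field(
        PreyFieldSimParams(grid_resolution=0.5, n_months=4, seed=7)
    )


@pytest.fixture()
def uniform_prey_field():
    return generate_prey_field(
        PreyFieldSimParams(grid_resolution=0.25, n_months=2, lognormal_cv=0.0,
                           mean_density=1.0, seed=0)
    )


@pytest.fixture(scope="session")
def reef_survey():
    return generate_reef_survey(ReefSimParams(n_islands=12, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
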