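import numpy as np
import pandas as pd
import pytest

from fpstgpr.synthetic import GeneratorParams, generate_world


@pytest.fixture(scope="session")
def small_world():
    """A compact but fully structured synthetic world shared across tests."""
    return generate_world(
        n_super_regions=2,
        n_regions_per_super=2,
        n_locations_per_region=2,
        years=range(2000, 2015),
        cadence=5,
        n_per_cell=300,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_microdata(small_world):
    return small_world.microdata()


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_records(weights, users, marital="partnered", **flags):
    """Tiny microdata frame builder for unit tests.

    ``users``: list of method strings ('' for non-user). Need flags default
    to a no-need configuration unless overridden.
    """
    n = len(weights)
    base = {
        "survey_id": ["S1"] * n,
        "location_id": ["L0"] * n,
        "year": [2010] * n,
        "age_group": ["25-29"] * n,
        "marital": [marital] * n,
        "methods": users,
        "sexually_active_4wk": [1.0] * n,
        "fecund": [0.0] * n,
        "wants_child_2yr": [0.0] * n,
        "pregnant_or_ppa": [0.0] * n,
        "pregnancy_wanted": [np.nan] * n,
        "weight": list(weights),
    }
    base.update(flags)
    return pd.DataFrame(base)
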