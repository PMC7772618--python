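import numpy as np
import pytest

import popenergy as pe


@pytest.fixture(scope="session")
def params():
    return pe.default_params()


@pytest.fixture(scope="session")
def small_config():
    """A small but realistic scenario: 12 years, ~40 captures/year."""
    return pe.ScenarioConfig(years=(1990, 2001), n_captures_per_year=40,
                             rng_seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return pe.generate_bundle(small_config)


@pytest.fixture(scope="session")
def small_profiles(small_bundle, params):
    return pe.profile_captures(small_bundle.captures, params)


@pytest.fixture(scope="session")
def small_composition(small_bundle):
    return pe.annual_composition(small_bundle.captures)


def make_record(bear_id="A1", year=2000, sex="F", age=6, offspring=False,
                length=195.0, girth=130.0):
    import datetime
    return pe.CaptureRecord(bear_id=bear_id, date=datetime.date(year, 9, 15),
                            sex=sex, age_years=age, with_offspring=offspring,
                            length_cm=length, girth_cm=girth)


@pytest.fixture
def record_factory():
    return make_record
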