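import datetime as dt

import numpy as np
import pytest

from incidentalg.synthetic import (
    ScenarioConfig,
    SiteConfig,
    generate_trials,
    study_like_scenario,
)
from incidentalg.trial_data import DecoyTrialRecord, default_calendars
from incidentalg.viewshed import calibrate_fall_distance


def make_record(**overrides) -> DecoyTrialRecord:
    """A valid trial record with any field overridden."""
    base = dict(
        site_id="Frontier I",
        turbine_id="T001",
        placement_date=dt.date(2021, 7, 10),
        distance_m=25.0,
        bearing_deg=135.0,
        viewshed_class="low",
        available=True,
        found=True,
        detection_date=dt.date(2021, 7, 18),
        activity="driving",
    )
    base.update(overrides)
    return DecoyTrialRecord(**base)


@pytest.fixture(scope="session")
def fall_model():
    return calibrate_fall_distance((33.0, 45.0, 61.0), r_max=100.0)


@pytest.fixture(scope="session")
def calendars():
    return default_calendars()


@pytest.fixture(scope="session")
def study_config():
    return study_like_scenario(seed=11)


@pytest.fixture(scope="session")
def study_records(study_config):
    return generate_trials(study_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def single_site_config():
    """One site, no random effect, flat coefficients: detection prob 0.5."""
    coeffs = {
        "intercept": 0.0,
        "density_quartile": {q: 0.0 for q in
                             ("near", "near_mid", "far_mid", "far")},
        "season_viewshed": {(s, v): 0.0
                            for s in ("spring", "summer", "fall", "winter")
                            for v in ("low", "moderate", "high")},
    }
    return ScenarioConfig(
        sites=[SiteConfig(site_id="Solo", n_turbines=10)],
        months=12,
        logit_coefficients=coeffs,
        site_sd=0.0,
        unavailable_fraction=0.0,
        seed=5,
    )
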