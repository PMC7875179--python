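from datetime import date

import pytest

from psyscreen.cohort_synth import make_published_funnel_fixture
from psyscreen.risk_model import (
    BaselineSurvival,
    ModelCoefficients,
    RiskModel,
    calibrate_exponential_baseline,
)
from psyscreen.screening_engine import StudyConfig


@pytest.fixture(scope="session")
def coeffs():
    return ModelCoefficients.published()


@pytest.fixture(scope="session")
def model(coeffs):
    return RiskModel(
        coeffs=coeffs,
        baseline=calibrate_exponential_baseline(coeffs),
        horizon_days=730,
    )


@pytest.fixture(scope="session")
def study_config():
    return StudyConfig(start_date=date(2018, 1, 1), end_date=date(2018, 12, 31))


@pytest.fixture(scope="session")
def funnel_fixture():
    return make_published_funnel_fixture()


@pytest.fixture
def flat_baseline():
    """Exponential baseline with S0(730) = 0.99."""
    import math

    return BaselineSurvival(form="exponential", rate=-math.log(0.99) / 730)
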