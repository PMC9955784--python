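import pytest
from hypothesis import HealthCheck, settings

from entroage import HEALTHY_PROFILE, Subject, default_db
from entroage.presets import diet

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def db():
    return default_db()


@pytest.fixture(scope="session")
def constants(db):
    return db.constants


@pytest.fixture(scope="session")
def healthy_profile():
    return HEALTHY_PROFILE


@pytest.fixture(scope="session")
def healthy_obese_diet():
    """3100 kcal plan for a 100 kg obese but otherwise healthy subject."""
    return diet("healthy_obese")


@pytest.fixture(scope="session")
def maintain_25_diet():
    """The 2210 kcal / 318-99-59 g plan for the 25-year-old 80 kg subject."""
    return diet("if_maintain_25")


@pytest.fixture(scope="session")
def obese_subject():
    return Subject(weight=100, height=170, age=40)
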