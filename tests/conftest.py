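import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vcarm.cohort import PatientRecord

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_record(
    patient_id="p0",
    age=45,
    er="negative",
    pr="negative",
    arm="AC",
    followup=10.0,
    event=0,
    s15=0.6,
):
    return PatientRecord(
        patient_id=patient_id,
        age=age,
        er_status=er,
        pr_status=pr,
        arm=arm,
        followup_years=followup,
        event=event,
        predicted_s15=s15,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def small_cohort():
    """Six records covering several subgroups, one ER+/PR+, one over-age."""
    return [
        make_record("a", age=30, er="negative", pr="negative", followup=15, event=0),
        make_record("b", age=45, er="positive", pr="negative", followup=7, event=1),
        make_record("c", age=39, er="negative", pr="positive", followup=12, event=1),
        make_record("d", age=52, er="negative", pr="negative", followup=15, event=0),
        make_record("e", age=45, er="positive", pr="positive", followup=15, event=0),
        make_record("f", age=61, er="negative", pr="negative", followup=15, event=0),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
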