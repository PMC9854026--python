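import dataclasses

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from vbacval import (
    AntenatalRecord,
    Cohort,
    IntrapartumRecord,
    default_config,
    generate_cohort,
)


def make_antenatal(**overrides) -> AntenatalRecord:
    base = dict(
        age=30.0,
        bmi_booking=25.0,
        prior_vaginal_delivery=False,
        prior_vbac=False,
        recurring_indication=False,
        htn_status="none",
        outcome="VBAC",
    )
    base.update(overrides)
    return AntenatalRecord(**base)


def make_intrapartum(**overrides) -> IntrapartumRecord:
    base = dict(
        age=30.0,
        bmi_booking=None,
        bmi_last_visit=28.0,
        gestational_age=39.0,
        prior_vaginal_delivery=False,
        prior_vbac=False,
        recurring_indication=False,
        htn_status="none",
        htn_flag=False,
        effacement=50.0,
        dilation=4.0,
        station=-2,
        induction=False,
        outcome="VBAC",
    )
    base.update(overrides)
    return IntrapartumRecord(**base)


@pytest.fixture
def antenatal_record():
    return make_antenatal()


@pytest.fixture
def intrapartum_record():
    return make_intrapartum()


@pytest.fixture
def small_antenatal_cohort():
    records = [
        make_antenatal(outcome="VBAC"),
        make_antenatal(age=35, bmi_booking=32, prior_vaginal_delivery=True, outcome="VBAC"),
        make_antenatal(age=40, recurring_indication=True, outcome="ERCS"),
    ]
    return Cohort(records, "antenatal", label="small")


@pytest.fixture
def synthetic_antenatal_cohort():
    return generate_cohort(default_config("antenatal", n=400, seed=42))


@pytest.fixture
def synthetic_intrapartum_cohort():
    return generate_cohort(default_config("intrapartum", n=400, seed=42))


def sub_seed(root: int, index: int) -> int:
    """Derive a replicate seed below 2**31 from a root seed."""
    return int(np.random.SeedSequence([root, index]).generate_state(1)[0] % (2**31))


def replace_config(config, **kw):
    return dataclasses.replace(config, **kw)
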