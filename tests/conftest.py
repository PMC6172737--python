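import numpy as np
import pandas as pd
import pytest

import retinasim as rs
from retinasim import config as cfg
from retinasim.records import Condition, Visit, VisitStatus, VisitType
from retinasim.synthetic import window_end


def make_record(pid, cond, visits, discharged_year=None):
    """visits: iterable of (date-like, VisitType, VisitStatus?)."""
    vs = []
    for v in visits:
        date, vtype = v[0], v[1]
        status = v[2] if len(v) > 2 else VisitStatus.attended
        vs.append(Visit(pd.Timestamp(date), vtype, status))
    vs.sort(key=lambda x: x.date)
    return rs.PatientRecord(pid, cond, vs, discharged_year)


@pytest.fixture(scope="session")
def reference_spec():
    return rs.reference_cohort_spec(seed=1)


@pytest.fixture(scope="session")
def reference_records(reference_spec):
    return rs.generate_cohort(reference_spec)


@pytest.fixture(scope="session")
def reference_as_of(reference_spec):
    return window_end(reference_spec)


@pytest.fixture(scope="session")
def small_spec():
    """A 150-patient cohort small enough for brute-force oracles."""
    return rs.CohortSpec(
        n_patients=150,
        mix={Condition.AMD: 0.2, Condition.DR: 0.4, Condition.MR: 0.4},
        category_counts={
            "injection": {Condition.AMD: 90, Condition.DR: 30, Condition.MR: 40},
            "injection_fu": {Condition.AMD: 120, Condition.DR: 40, Condition.MR: 50},
            "laser": {Condition.DR: 10},
            "laser_fu": {Condition.DR: 15},
            "observation": {Condition.AMD: 30, Condition.DR: 80, Condition.MR: 75},
        },
        discharge_counts={
            (Condition.AMD, "treated", 1): 1,
            (Condition.DR, "observation", 1): 8,
            (Condition.MR, "observation", 2): 3,
        },
        treated_counts={Condition.AMD: 12, Condition.DR: 8, Condition.MR: 10},
        eligible_planted=25,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_records(small_spec):
    return rs.generate_cohort(small_spec)


def tiny_scenario(name="Current Service", regimen=None, virtual_clinic=False,
                  seed=0, replications=2, horizon_months=8, warmup_months=2,
                  monthly_arrivals=40.0, n_init=60, eligible=20, **overrides):
    """Desk-scale scenario for fast engine tests."""
    ov = {
        "simulation": {"monthly_new_arrivals": monthly_arrivals},
        "initial_cohort": {"n": n_init, "eligible": eligible},
    }
    for k, v in overrides.items():
        ov.setdefault(k, {}).update(v)
    return cfg.build_scenario(
        name, regimen or rs.RegimenSpec.prn(), virtual_clinic,
        seed=seed, replications=replications, horizon_months=horizon_months,
        warmup_months=warmup_months, overrides=ov,
    )


@pytest.fixture
def tiny_scenario_factory():
    return tiny_scenario
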