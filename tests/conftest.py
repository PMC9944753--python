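import numpy as np
import pytest

from ehrcausal import SimConfig, StudyConfig, generate_population, build_cohort
from ehrcausal.synth import PatientRecord
from ehrcausal.config import DAYS_PER_YEAR


def day_of_year(year: float) -> int:
    """Integer day index of a (possibly fractional) calendar year."""
    return round((year - 1970) * DAYS_PER_YEAR)


def make_patient(pid=0, sex="F", birth_year=1940.0, smoking="never",
                 events=(), sbp=(), censor_day=None, death_day=None,
                 death_cause=None, **cov):
    """Hand-built patient for boundary-case tests."""
    covariates = {"bmi": 28.0, "hdl": 1.3, "total_chol": 5.0,
                  "triglycerides": 1.8, "af": 0, "ckd": 0,
                  "antihypertensive_baseline": 0, "insulin_baseline": 0,
                  "hba1c_mean": 7.5, "diabetes_duration": 5.0}
    covariates.update(cov)
    return PatientRecord(
        pid=pid, sex=sex, birth_day=day_of_year(birth_year), smoking=smoking,
        covariates=covariates, events=sorted(events, key=lambda t: (t[0], t[1])),
        sbp_measurements=list(sbp), censor_day=censor_day, death_day=death_day,
        death_cause=death_cause)


@pytest.fixture(scope="session")
def study_config():
    return StudyConfig()


@pytest.fixture(scope="session")
def small_population():
    return generate_population(SimConfig(n_patients=800, seed=123))


@pytest.fixture(scope="session")
def small_cohort(small_population, study_config):
    cohort, flow = build_cohort(small_population, study_config, fold_seed=9)
    return cohort, flow
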