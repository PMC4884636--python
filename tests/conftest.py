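import numpy as np
import pytest

from nodestrat import (
    LifeTable,
    PatientRecord,
    default_cohort_spec,
    generate_cohort,
    synthetic_life_table,
)


def make_record(
    patient_id="p0",
    age_at_dx=62,
    race="white",
    dx_year=2000,
    follow_up_months=120,
    vital_status="censored",
    nodes_examined=10,
    nodes_positive=1,
    grade="III",
    radiation="no",
):
    return PatientRecord(
        patient_id=patient_id,
        age_at_dx=age_at_dx,
        sex="male",
        race=race,
        dx_year=dx_year,
        follow_up_months=follow_up_months,
        vital_status=vital_status,
        nodes_examined=nodes_examined,
        nodes_positive=nodes_positive,
        grade=grade,
        radiation=radiation,
    )


def uniform_life_table(p=1.0, ages=(30, 110), years=(1980, 2045)):
    """Life table with the same annual survival everywhere."""
    ages_ = np.arange(ages[0], ages[1] + 1)
    years_ = np.arange(years[0], years[1] + 1)
    races = ("white", "black", "other")
    values = np.full((1, len(races), len(ages_), len(years_)), float(p))
    return LifeTable(("male",), races, ages_, years_, values)


@pytest.fixture(scope="session")
def flat_table():
    """All-1.0 life table: expected survival is identically 1."""
    return uniform_life_table(1.0)


@pytest.fixture(scope="session")
def synth_table():
    return synthetic_life_table()


@pytest.fixture(scope="session")
def small_cohort(synth_table):
    """Three-stratum synthetic cohort, n=200/stratum — cheap shared input."""
    return generate_cohort(default_cohort_spec(n_per_stratum=200, seed=7), synth_table)
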