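import datetime as dt

import pytest

from crwscreen.cohort import MealIntake, MnaInterview, PatientRecord, WeightHistory

ADMISSION = dt.date(2021, 6, 1)


def make_meals(principal=10, side=10, days=3, start=ADMISSION):
    return tuple(
        MealIntake(date=start + dt.timedelta(days=d), slot=slot,
                   principal_score=principal, side_score=side)
        for d in range(days)
        for slot in ("breakfast", "lunch", "dinner")
    )


def make_record(
    patient_id="P1",
    age=75,
    sex="F",
    diagnosis="cerebrovascular",
    transferred=False,
    height=1.60,
    admission_weight=55.0,
    prior_weight=55.0,
    gap_days=14,
    albumin=4.0,
    decubitus=False,
    digestive=False,
    tpn=False,
    meals=None,
    mna=None,
):
    """A fully populated, healthy-by-default record; tweak per test."""
    history = WeightHistory(
        admission_weight=admission_weight,
        admission_date=ADMISSION,
        prior_weight=prior_weight,
        prior_weight_date=None if prior_weight is None else ADMISSION - dt.timedelta(days=gap_days),
    )
    return PatientRecord(
        patient_id=patient_id,
        age=age,
        sex=sex,
        diagnosis=diagnosis,
        transferred_to_acute=transferred,
        height=height,
        weight_history=history,
        serum_albumin=albumin,
        decubitus=decubitus,
        digestive_symptoms=digestive,
        tpn=tpn,
        meals=make_meals() if meals is None else meals,
        mna=mna,
    )


BEST_INTERVIEW = MnaInterview(
    intake_decline="none",
    weight_loss_3mo="none",
    mobility="outdoors",
    stress="no_stress",
    neuropsych="none",
)

WORST_INTERVIEW = MnaInterview(
    intake_decline="severe",
    weight_loss_3mo="gt3kg",
    mobility="bed_or_chair",
    stress="under_stress",
    neuropsych="severe",
)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def small_cohort():
    from crwscreen.synthetic import default_simulation_config, generate_cohort

    return generate_cohort(default_simulation_config(n=40, seed=7))
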