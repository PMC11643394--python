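import datetime as dt
import textwrap

import pytest

from crwscreen.cohort import (
    MealIntake,
    PatientRecord,
    RowParseError,
    SchemaError,
    WeightHistory,
    filter_complete,
    filter_eligible,
    read_cohort_csv,
    write_cohort_csv,
)

from conftest import make_record

PATIENT_HEADER = (
    "patient_id,age,sex,diagnosis,transferred,height_m,adm_weight_kg,adm_date,"
    "prior_weight_kg,prior_weight_date,albumin_gdl,decubitus,digestive,tpn,"
    "mna_intake_decline,mna_weight_loss,mna_mobility,mna_stress,mna_neuropsych"
)


def _write(tmp_path, patients_body, meals_body=""):
    p = tmp_path / "patients.csv"
    m = tmp_path / "meals.csv"
    p.write_text(PATIENT_HEADER + "\n" + textwrap.dedent(patients_body))
    m.write_text("patient_id,date,slot,principal_score,side_score\n" + textwrap.dedent(meals_body))
    return p, m


def test_read_joins_meals_per_patient(tmp_path):
    meals = "".join(
        f"{pid},2021-06-0{d},{slot},8,7\n"
        for pid in ("A", "B")
        for d in (1, 2, 3)
        for slot in ("breakfast", "lunch", "dinner")
    )
    p, m = _write(
        tmp_path,
        "A,77,F,cerebrovascular,0,1.6,55.0,2021-06-01,56.0,2021-05-18,3.8,0,0,0,none,none,indoors,no_stress,none\n"
        "B,80,M,cerebrovascular,0,1.7,60.0,2021-06-01,,,,1,0,0,,,,,\n",
        meals,
    )
    cohort = read_cohort_csv(p, m)
    assert len(cohort) == 2
    assert all(len(r.meals) == 9 for r in cohort)
    a, b = cohort
    assert a.mna is not None and a.mna.mobility == "indoors"
    # blank optional fields are explicit missing markers, not zeros
    assert b.mna is None
    assert b.serum_albumin is None
    assert b.weight_history.prior_weight is None
    assert b.decubitus is True


def test_missing_required_column_is_schema_error(tmp_path):
    p = tmp_path / "patients.csv"
    p.write_text(PATIENT_HEADER.replace("height_m,", "") + "\n")
    with pytest.raises(SchemaError, match="height_m"):
        read_cohort_csv(p)


def test_empty_data_section_gives_empty_cohort(tmp_path):
    p, m = _write(tmp_path, "")
    assert read_cohort_csv(p, m) == []


def test_unparseable_cell_reports_row(tmp_path):
    p, m = _write(
        tmp_path,
        "A,77,F,cerebrovascular,0,1.6,55.0,not-a-date,,,,0,0,0,,,,,\n",
    )
    with pytest.raises(RowParseError, match="row 0"):
        read_cohort_csv(p, m)


def test_schema_remap(tmp_path):
    p = tmp_path / "p.csv"
    p.write_text(PATIENT_HEADER.replace("height_m", "Height") + "\n"
                 "A,77,F,cerebrovascular,0,1.6,55.0,2021-06-01,,,,0,0,0,,,,,\n")
    cohort = read_cohort_csv(p, patient_schema={"height_m": "Height"})
    assert cohort[0].height == 1.6


@pytest.mark.parametrize("seed", [0, 11])
def test_roundtrip_is_lossless(tmp_path, seed):
    from crwscreen.synthetic import default_simulation_config, generate_cohort

    cohort = generate_cohort(default_simulation_config(n=25, seed=seed))
    write_cohort_csv(cohort, tmp_path / "p.csv", tmp_path / "m.csv")
    back = read_cohort_csv(tmp_path / "p.csv", tmp_path / "m.csv")
    assert back == cohort


def test_eligibility_reasons():
    cohort = [
        make_record("boundary", age=65),
        make_record("kept", age=66),
        make_record("moved", age=70, transferred=True),
        make_record("other-dx", age=70, diagnosis="orthopedic"),
    ]
    kept, excluded = filter_eligible(cohort)
    assert [r.patient_id for r in kept] == ["kept"]
    reasons = {e.record.patient_id: e.reasons for e in excluded}
    assert reasons == {"boundary": ("age",), "moved": ("transfer",), "other-dx": ("diagnosis",)}
    # the inclusive reading is one config knob away
    kept65, _ = filter_eligible(cohort, min_age=65)
    assert {r.patient_id for r in kept65} == {"boundary", "kept"}


def test_filters_partition_the_cohort(small_cohort):
    for filt in (filter_eligible, lambda c: filter_complete(c, ("serum_albumin", "mna"))):
        kept, excluded = filt(small_cohort)
        ids = [r.patient_id for r in kept] + [e.record.patient_id for e in excluded]
        assert sorted(ids) == sorted(r.patient_id for r in small_cohort)
        assert set(r.patient_id for r in kept).isdisjoint(e.record.patient_id for e in excluded)


def test_completeness_logs_missing_fields():
    complete = make_record("ok")
    no_alb = make_record("no-alb", albumin=None)
    no_meals = make_record("no-meals", albumin=None, meals=())
    kept, excluded = filter_complete([complete, no_alb, no_meals], ("serum_albumin", "meals"))
    assert [r.patient_id for r in kept] == ["ok"]
    assert {e.record.patient_id: e.reasons for e in excluded} == {
        "no-alb": ("serum_albumin",),
        "no-meals": ("serum_albumin", "meals"),
    }
    assert filter_complete([], ("serum_albumin",)) == ([], [])


def test_domain_invariants_enforced():
    with pytest.raises(ValueError):
        MealIntake(dt.date(2021, 6, 1), "breakfast", 11, 0)
    with pytest.raises(ValueError):
        MealIntake(dt.date(2021, 6, 1), "brunch", 5, 5)
    with pytest.raises(ValueError):
        WeightHistory(55.0, dt.date(2021, 6, 1), 56.0, dt.date(2021, 6, 2))
    with pytest.raises(ValueError):
        make_record(height=0.3)
    with pytest.raises(ValueError):
        make_record(albumin=0.5)
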