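import datetime as dt
from itertools import product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crwscreen.cohort import WeightHistory
from crwscreen.jmethod import (
    MALNUTRITION,
    NON_MALNUTRITION,
    JMethodConfig,
    JMethodResult,
    MissingDataError,
    UndefinedRateError,
    classify_jmethod,
    compute_bmi,
    evaluate_criteria,
    mean_daily_intake_pct,
    screen_jmethod,
    weekly_weight_change,
)

from conftest import ADMISSION, make_meals, make_record


def _history(prior, admission, gap):
    return WeightHistory(
        admission_weight=admission,
        admission_date=ADMISSION,
        prior_weight=prior,
        prior_weight_date=ADMISSION - dt.timedelta(days=gap),
    )


@pytest.mark.parametrize(
    "prior,admission,gap,expected",
    [
        (60.0, 58.8, 14, -1.0),   # 2% drop over two weeks -> 1 %/week loss
        (55.0, 55.0, 10, 0.0),
        (50.0, 49.0, 7, -2.0),
        (50.0, 51.0, 7, 2.0),     # gain is positive
    ],
)
def test_weekly_weight_change(prior, admission, gap, expected):
    assert weekly_weight_change(_history(prior, admission, gap)) == pytest.approx(expected)


def test_weight_change_guards():
    with pytest.raises(UndefinedRateError):
        weekly_weight_change(_history(55.0, 55.0, 0))
    with pytest.raises(MissingDataError):
        weekly_weight_change(WeightHistory(55.0, ADMISSION))


@given(
    prior=st.floats(30, 120),
    admission=st.floats(30, 120),
    gap=st.integers(1, 60),
    scale=st.floats(0.5, 2.0),
)
@settings(max_examples=100, derandomize=True)
def test_weight_change_scale_invariant(prior, admission, gap, scale):
    """The rate depends only on relative change: rescaling both weights
    leaves it unchanged, and a 7-day gap gives the plain percent change."""
    base = weekly_weight_change(_history(prior, admission, gap))
    scaled = weekly_weight_change(_history(prior * scale, admission * scale, gap))
    assert scaled == pytest.approx(base, rel=1e-9)
    week = weekly_weight_change(_history(prior, admission, 7))
    assert week == pytest.approx((admission - prior) / prior * 100.0)


def test_bmi():
    assert compute_bmi(59.17, 1.60) == pytest.approx(23.1, abs=0.05)
    assert compute_bmi(46.0, 1.60) == pytest.approx(17.97, abs=0.01)
    assert compute_bmi(46.0, 1.60) < 18.5  # criterion boundary side
    with pytest.raises(ValueError):
        compute_bmi(60.0, 0.0)


@pytest.mark.parametrize(
    "score,expected",
    [(10, 100.0), (4, 40.0), (5, 50.0), (0, 0.0)],
)
def test_mean_intake(score, expected):
    meals = make_meals(principal=score, side=score)
    assert mean_daily_intake_pct(meals, ADMISSION) == pytest.approx(expected)


def test_intake_window_and_missing():
    late = make_meals(start=ADMISSION + dt.timedelta(days=5))
    with pytest.raises(MissingDataError):
        mean_daily_intake_pct(late, ADMISSION)
    mixed = make_meals(principal=2, side=2) + make_meals(principal=10, side=10,
                                                         start=ADMISSION + dt.timedelta(days=3))
    # only the first 3 days count
    assert mean_daily_intake_pct(mixed, ADMISSION) == pytest.approx(20.0)


@given(
    scores=st.lists(st.tuples(st.integers(0, 10), st.integers(0, 10)), min_size=1, max_size=12),
    wp=st.floats(0.0, 1.0),
)
@settings(max_examples=100, derandomize=True)
def test_mean_intake_bounded(scores, wp):
    meals = tuple(
        make_meals(principal=p, side=s, days=1)[i % 3]
        for i, (p, s) in enumerate(scores)
    )
    config = JMethodConfig(principal_side_weights=(wp, 1.0 - wp))
    assert 0.0 <= mean_daily_intake_pct(meals, ADMISSION, config) <= 100.0


def test_criteria_flags_and_count():
    # BMI 17.0 and albumin 2.9 met, everything else healthy
    record = make_record(admission_weight=43.52, prior_weight=43.52, height=1.6,
                         albumin=2.9, meals=make_meals(principal=8, side=8))
    res = evaluate_criteria(record)
    assert res.criteria == {
        "weight_loss": False,
        "low_intake": False,
        "low_bmi": True,
        "low_albumin": True,
        "decubitus": False,
        "misc": False,
    }
    assert res.n_non_decubitus_met == 2
    assert classify_jmethod(res) == MALNUTRITION


def test_criterion_boundaries():
    # albumin "up to 3.0" is inclusive
    assert evaluate_criteria(make_record(albumin=3.0)).criteria["low_albumin"]
    assert not evaluate_criteria(make_record(albumin=3.01)).criteria["low_albumin"]
    # intake exactly at 50% does not meet the strict "<" criterion
    half = make_record(meals=make_meals(principal=5, side=5))
    assert not evaluate_criteria(half).criteria["low_intake"]
    # weight loss of exactly 1 %/week does not meet the strict ">" criterion
    at_1pct = make_record(admission_weight=54.45, prior_weight=55.0, gap_days=7)
    assert not evaluate_criteria(at_1pct).criteria["weight_loss"]


def test_healthy_record_is_negative():
    res = screen_jmethod(make_record())
    assert not any(res.criteria.values())
    assert res.classification == NON_MALNUTRITION


def test_decubitus_alone_is_sufficient():
    res = screen_jmethod(make_record(decubitus=True))
    assert sum(res.criteria.values()) == 1
    assert res.classification == MALNUTRITION


def test_two_criteria_meet_default_threshold():
    res_flags = JMethodResult(None, None, None, None, 22.0, {
        "weight_loss": True, "low_intake": True, "low_bmi": False,
        "low_albumin": False, "decubitus": False, "misc": False,
    })
    assert classify_jmethod(res_flags) == MALNUTRITION
    assert classify_jmethod(res_flags, JMethodConfig(criterion_count_threshold=3)) == NON_MALNUTRITION


def test_classification_monotone_in_flags():
    """Turning any criterion on can never rescue a malnourished label."""
    names = ("weight_loss", "low_intake", "low_bmi", "low_albumin", "decubitus", "misc")
    for flags in product((False, True), repeat=6):
        base = JMethodResult(None, None, None, None, 22.0, dict(zip(names, flags)))
        label = classify_jmethod(base)
        for k, name in enumerate(names):
            if not flags[k]:
                bumped = dict(zip(names, flags))
                bumped[name] = True
                worse = JMethodResult(None, None, None, None, 22.0, bumped)
                if label == MALNUTRITION:
                    assert classify_jmethod(worse) == MALNUTRITION


def test_missing_policy():
    record = make_record(prior_weight=None, albumin=None)
    res = evaluate_criteria(record)  # default: absent evidence scores not-met
    assert res.weekly_weight_change_pct is None
    assert not res.criteria["weight_loss"] and not res.criteria["low_albumin"]
    with pytest.raises(MissingDataError):
        evaluate_criteria(record, JMethodConfig(missing_policy="exclude_patient"))
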