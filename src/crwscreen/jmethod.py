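"""The J-Method: a record-only nutritional screen for rehabilitation wards.

Six criteria are read off the ward chart, with no patient interview:

1. body-weight loss faster than 1 % per week (weekly rate computed from
   the admission weight and the latest pre-admission weight),
2. mean daily food intake below 50 % over the first 3 days on the ward,
3. BMI below 18.5 kg/m2,
4. serum albumin at or below 3.0 g/dL,
5. decubitus (pressure ulcer) anywhere on the body,
6. miscellaneous: digestive symptoms (nausea/vomiting/diarrhoea) or
   total parenteral nutrition.

Decubitus alone classifies the patient as malnourished; otherwise the
patient is malnourished when at least ``criterion_count_threshold`` of
the remaining five criteria are met (default 2 — the wording "more than
two" is ambiguous between >=2 and >=3, so the count is configurable).

All thresholds, the intake window, the principal/side weighting and the
missing-data policy live in :class:`JMethodConfig` so every screening
decision is explicit and auditable.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace
from typing import Sequence

from .cohort import MealIntake, PatientRecord, WeightHistory

__all__ = [
    "JMethodConfig",
    "JMethodResult",
    "MissingDataError",
    "UndefinedRateError",
    "weekly_weight_change",
    "compute_bmi",
    "mean_daily_intake_pct",
    "intake_component_means",
    "evaluate_criteria",
    "classify_jmethod",
    "screen_jmethod",
]

MALNUTRITION = "malnutrition"
NON_MALNUTRITION = "non_malnutrition"

CRITERION_NAMES = ("weight_loss", "low_intake", "low_bmi", "low_albumin", "decubitus", "misc")


class MissingDataError(ValueError):
    """A criterion's inputs are missing and the policy is to exclude."""


class UndefinedRateError(ValueError):
    """Weight-change rate is undefined (zero-day measurement gap)."""


@dataclass(frozen=True)
class JMethodConfig:
    """Thresholds and policies of the screen.

    ``missing_policy`` governs criteria whose inputs are absent:
    ``"criterion_not_met"`` (default) scores them as not met, so absent
    evidence never pushes a patient toward malnutrition;
    ``"exclude_patient"`` raises :class:`MissingDataError` instead so the
    caller can drop the record.
    """

    weight_loss_pct_per_week: float = 1.0
    intake_pct_threshold: float = 50.0
    intake_window_days: int = 3
    bmi_threshold: float = 18.5
    albumin_threshold: float = 3.0
    criterion_count_threshold: int = 2
    principal_side_weights: tuple[float, float] = (0.5, 0.5)
    missing_policy: str = "criterion_not_met"

    def __post_init__(self) -> None:
        for name in (
            "weight_loss_pct_per_week",
            "intake_pct_threshold",
            "bmi_threshold",
            "albumin_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.intake_window_days < 1:
            raise ValueError("intake_window_days must be >= 1")
        if self.criterion_count_threshold not in range(1, 6):
            raise ValueError("criterion_count_threshold must be in 1..5")
        wp, ws = self.principal_side_weights
        if wp < 0 or ws < 0 or abs(wp + ws - 1.0) > 1e-9:
            raise ValueError("principal_side_weights must be nonnegative and sum to 1")
        if self.missing_policy not in ("criterion_not_met", "exclude_patient"):
            raise ValueError("missing_policy must be criterion_not_met or exclude_patient")


@dataclass(frozen=True)
class JMethodResult:
    """Per-patient screening output: intermediate quantities, the six
    criterion flags and (after classification) the binary label.

    ``weekly_weight_change_pct`` is signed: negative means loss.
    """

    weekly_weight_change_pct: float | None
    mean_intake_pct: float | None
    mean_principal_pct: float | None
    mean_side_pct: float | None
    bmi: float
    criteria: dict[str, bool]
    classification: str | None = None

    @property
    def n_non_decubitus_met(self) -> int:
        return sum(self.criteria[name] for name in CRITERION_NAMES if name != "decubitus")


def weekly_weight_change(history: WeightHistory) -> float:
    """Signed weight change in percent per week.

    ``((admission - prior) / prior) * (7 / day_gap) * 100`` — the percent
    change relative to the pre-admission weight, rescaled to a 7-day
    window.  Negative values denote loss.
    """
    if history.prior_weight is None:
        raise MissingDataError("prior weight missing; weekly change undefined")
    gap = history.day_gap
    if gap == 0:
        raise UndefinedRateError("weight measurements on the same day; rate undefined")
    return (
        (history.admission_weight - history.prior_weight)
        / history.prior_weight
        * (7.0 / gap)
        * 100.0
    )


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index, weight (kg) / height (m) squared."""
    if height <= 0:
        raise ValueError("height must be positive")
    return weight / height**2


def _meal_pct(meal: MealIntake, config: JMethodConfig) -> float:
    wp, ws = config.principal_side_weights
    return (wp * meal.principal_score + ws * meal.side_score) * 10.0


def _in_window(meals: Sequence[MealIntake], admission_date: dt.date, window: int):
    end = admission_date + dt.timedelta(days=window)
    return [m for m in meals if admission_date <= m.date < end]


def mean_daily_intake_pct(
    meals: Sequence[MealIntake],
    admission_date: dt.date,
    config: JMethodConfig = JMethodConfig(),
) -> float:
    """Mean intake percentage over meals in the post-admission window.

    Each meal contributes the weighted combination of its principal-food
    and side-dish scores, scaled to percent; the mean is over all meals
    recorded within ``intake_window_days`` of admission.
    """
    window = _in_window(meals, admission_date, config.intake_window_days)
    if not window:
        raise MissingDataError("no meals recorded in the intake window")
    return sum(_meal_pct(m, config) for m in window) / len(window)


def intake_component_means(
    meals: Sequence[MealIntake],
    admission_date: dt.date,
    config: JMethodConfig = JMethodConfig(),
) -> tuple[float, float]:
    """(principal, side) mean intake percentages over the window —
    reported separately because the two components behave differently in
    poorly-eating patients."""
    window = _in_window(meals, admission_date, config.intake_window_days)
    if not window:
        raise MissingDataError("no meals recorded in the intake window")
    n = len(window)
    principal = sum(m.principal_score for m in window) * 10.0 / n
    side = sum(m.side_score for m in window) * 10.0 / n
    return principal, side


def evaluate_criteria(record: PatientRecord, config: JMethodConfig = JMethodConfig()) -> JMethodResult:
    """Evaluate the six criteria on one record; classification left unset."""

    def missing(what: str):
        if config.missing_policy == "exclude_patient":
            raise MissingDataError(f"{what} missing for patient {record.patient_id}")
        return None

    try:
        change = weekly_weight_change(record.weight_history)
    except MissingDataError:
        change = missing("prior weight")
    weight_loss = change is not None and change < -config.weight_loss_pct_per_week

    try:
        intake = mean_daily_intake_pct(record.meals, record.weight_history.admission_date, config)
        principal, side = intake_component_means(
            record.meals, record.weight_history.admission_date, config
        )
    except MissingDataError:
        intake = missing("meal log")
        principal = side = None
    low_intake = intake is not None and intake < config.intake_pct_threshold

    bmi = compute_bmi(record.weight_history.admission_weight, record.height)
    low_bmi = bmi < config.bmi_threshold

    if record.serum_albumin is None:
        alb = missing("serum albumin")
    else:
        alb = record.serum_albumin
    low_albumin = alb is not None and alb <= config.albumin_threshold  # "up to 3.0" is inclusive

    return JMethodResult(
        weekly_weight_change_pct=change,
        mean_intake_pct=intake,
        mean_principal_pct=principal,
        mean_side_pct=side,
        bmi=bmi,
        criteria={
            "weight_loss": weight_loss,
            "low_intake": low_intake,
            "low_bmi": low_bmi,
            "low_albumin": low_albumin,
            "decubitus": record.decubitus,
            "misc": record.digestive_symptoms or record.tpn,
        },
    )


def classify_jmethod(result: JMethodResult, config: JMethodConfig = JMethodConfig()) -> str:
    """Binary decision: decubitus alone suffices, otherwise at least
    ``criterion_count_threshold`` of the other five criteria."""
    if result.criteria["decubitus"] or result.n_non_decubitus_met >= config.criterion_count_threshold:
        return MALNUTRITION
    return NON_MALNUTRITION


def screen_jmethod(record: PatientRecord, config: JMethodConfig = JMethodConfig()) -> JMethodResult:
    """Evaluate criteria and attach the classification."""
    result = evaluate_criteria(record, config)
    return replace(result, classification=classify_jmethod(result, config))
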