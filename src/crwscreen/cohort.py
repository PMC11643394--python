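"""Patient-level domain model, CSV I/O and study-entry filters.

The cohort is a convalescent rehabilitation ward (CRW) population: older
adults admitted after an acute event (typically cerebrovascular disease)
whose nutritional state must be screened from ward records within days of
admission.  Records carry the anthropometry, labs and flags the screening
criteria need, a per-meal intake log scored 0-10 by nursing staff, and an
optional MNA-SF interview.

Two plain-text CSV files describe a cohort: one row per patient plus one
row per meal, joined on ``patient_id``.  Column names are remappable so
exports from different record systems can be read without editing them.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "WeightHistory",
    "MealIntake",
    "MnaInterview",
    "PatientRecord",
    "SchemaError",
    "RowParseError",
    "read_cohort_csv",
    "write_cohort_csv",
    "filter_eligible",
    "filter_complete",
    "Exclusion",
]

MEAL_SLOTS = ("breakfast", "lunch", "dinner")

INTAKE_DECLINE_LEVELS = ("severe", "moderate", "none")
WEIGHT_LOSS_LEVELS = ("gt3kg", "unknown", "1to3kg", "none")
MOBILITY_LEVELS = ("bed_or_chair", "indoors", "outdoors")
STRESS_LEVELS = ("under_stress", "no_stress")
NEUROPSYCH_LEVELS = ("severe", "moderate", "none")


class SchemaError(ValueError):
    """A required column is absent from an input CSV."""


class RowParseError(ValueError):
    """A row holds a value that cannot be parsed; carries the row index."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


def _check_category(value: str, allowed: Sequence[str], name: str) -> None:
    if value not in allowed:
        raise ValueError(f"{name} must be one of {allowed}, got {value!r}")


@dataclass(frozen=True)
class WeightHistory:
    """Admission body weight plus the latest pre-admission measurement.

    The pre-admission ("prior") weight comes from the referring acute
    hospital; its date gives the day gap used to express weight change as
    a weekly rate.  Prior fields may be missing when the referring
    hospital recorded no weight.
    """

    admission_weight: float
    admission_date: dt.date
    prior_weight: float | None = None
    prior_weight_date: dt.date | None = None

    def __post_init__(self) -> None:
        if self.admission_weight <= 0:
            raise ValueError("admission_weight must be positive")
        if self.prior_weight is not None and self.prior_weight <= 0:
            raise ValueError("prior_weight must be positive")
        if (self.prior_weight is None) != (self.prior_weight_date is None):
            raise ValueError("prior weight and its date must be given together")
        if self.prior_weight_date is not None and self.prior_weight_date > self.admission_date:
            raise ValueError("prior_weight_date must not be after admission_date")

    @property
    def day_gap(self) -> int | None:
        """Whole days from the prior measurement to admission, or None."""
        if self.prior_weight_date is None:
            return None
        return (self.admission_date - self.prior_weight_date).days


@dataclass(frozen=True)
class MealIntake:
    """One meal's intake, scored visually by ward nursing staff.

    ``principal_score`` and ``side_score`` are integers 0-10: tenths of
    the served principal food (staple) and side dishes actually eaten.
    """

    date: dt.date
    slot: str
    principal_score: int
    side_score: int

    def __post_init__(self) -> None:
        _check_category(self.slot, MEAL_SLOTS, "slot")
        for name in ("principal_score", "side_score"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool) or not 0 <= v <= 10:
                raise ValueError(f"{name} must be an integer in [0, 10], got {v!r}")


@dataclass(frozen=True)
class MnaInterview:
    """The five interview items of the MNA-SF (the sixth item, BMI, comes
    from the chart, not the interview)."""

    intake_decline: str
    weight_loss_3mo: str
    mobility: str
    stress: str
    neuropsych: str

    def __post_init__(self) -> None:
        _check_category(self.intake_decline, INTAKE_DECLINE_LEVELS, "intake_decline")
        _check_category(self.weight_loss_3mo, WEIGHT_LOSS_LEVELS, "weight_loss_3mo")
        _check_category(self.mobility, MOBILITY_LEVELS, "mobility")
        _check_category(self.stress, STRESS_LEVELS, "stress")
        _check_category(self.neuropsych, NEUROPSYCH_LEVELS, "neuropsych")


@dataclass(frozen=True)
class PatientRecord:
    """One admitted patient, as screened from the ward record."""

    patient_id: str
    age: int
    sex: str
    diagnosis: str
    transferred_to_acute: bool
    height: float  # metres
    weight_history: WeightHistory
    serum_albumin: float | None = None  # g/dL
    decubitus: bool = False
    digestive_symptoms: bool = False
    tpn: bool = False
    meals: tuple[MealIntake, ...] = field(default_factory=tuple)
    mna: MnaInterview | None = None

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("age must be nonnegative")
        _check_category(self.sex, ("F", "M"), "sex")
        if not 0.5 < self.height < 2.5:
            raise ValueError(f"height must be in (0.5, 2.5) m, got {self.height}")
        if self.serum_albumin is not None and not 1.0 < self.serum_albumin < 6.0:
            raise ValueError(f"serum_albumin must be in (1.0, 6.0) g/dL, got {self.serum_albumin}")
        object.__setattr__(self, "meals", tuple(self.meals))


# ---------------------------------------------------------------------------
# CSV schema

#: canonical name -> default column header, patient file
PATIENT_COLUMNS = {
    "patient_id": "patient_id",
    "age": "age",
    "sex": "sex",
    "diagnosis": "diagnosis",
    "transferred": "transferred",
    "height_m": "height_m",
    "adm_weight_kg": "adm_weight_kg",
    "adm_date": "adm_date",
    "prior_weight_kg": "prior_weight_kg",
    "prior_weight_date": "prior_weight_date",
    "albumin_gdl": "albumin_gdl",
    "decubitus": "decubitus",
    "digestive": "digestive",
    "tpn": "tpn",
    "mna_intake_decline": "mna_intake_decline",
    "mna_weight_loss": "mna_weight_loss",
    "mna_mobility": "mna_mobility",
    "mna_stress": "mna_stress",
    "mna_neuropsych": "mna_neuropsych",
}

MEAL_COLUMNS = {
    "patient_id": "patient_id",
    "date": "date",
    "slot": "slot",
    "principal_score": "principal_score",
    "side_score": "side_score",
}

# columns that may be absent from the file entirely (MNA-SF interview is
# optional: the record-only screening path needs no interview at all)
_OPTIONAL_PATIENT_COLUMNS = {
    "prior_weight_kg",
    "prior_weight_date",
    "albumin_gdl",
    "mna_intake_decline",
    "mna_weight_loss",
    "mna_mobility",
    "mna_stress",
    "mna_neuropsych",
}

_MNA_FIELDS = {
    "mna_intake_decline": "intake_decline",
    "mna_weight_loss": "weight_loss_3mo",
    "mna_mobility": "mobility",
    "mna_stress": "stress",
    "mna_neuropsych": "neuropsych",
}


def _resolve_schema(defaults: Mapping[str, str], schema: Mapping[str, str] | None) -> dict[str, str]:
    cols = dict(defaults)
    if schema:
        unknown = set(schema) - set(defaults)
        if unknown:
            raise SchemaError(f"unknown schema keys: {sorted(unknown)}")
        cols.update(schema)
    return cols


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and pd.isna(value)) or value == ""


def _parse_date(value, row: int, what: str) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise RowParseError(row, f"unparseable {what} {value!r}") from exc


def _parse_float(value, row: int, what: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise RowParseError(row, f"unparseable {what} {value!r}") from exc


def _parse_int(value, row: int, what: str) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError) as exc:
        raise RowParseError(row, f"unparseable {what} {value!r}") from exc
    if f != int(f):
        raise RowParseError(row, f"{what} must be an integer, got {value!r}")
    return int(f)


_TRUE = {"1", "true", "yes", "y", "t"}
_FALSE = {"0", "false", "no", "n", "f", ""}


def _parse_bool(value, row: int, what: str) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE or _is_missing(value):
        return False
    raise RowParseError(row, f"unparseable boolean {what} {value!r}")


def read_cohort_csv(
    patients_path,
    meals_path=None,
    *,
    patient_schema: Mapping[str, str] | None = None,
    meal_schema: Mapping[str, str] | None = None,
) -> list[PatientRecord]:
    """Read a cohort from the patient CSV and (optionally) the meal CSV.

    Meal rows are joined onto patients by ``patient_id``.  Optional
    fields left blank become explicit missing markers (``None``), never
    zeros.  Raises :class:`SchemaError` for an absent required column and
    :class:`RowParseError` (carrying the offending row index) for an
    unparseable cell.
    """
    pcols = _resolve_schema(PATIENT_COLUMNS, patient_schema)
    patients = pd.read_csv(patients_path, dtype=str, keep_default_na=False)
    required = [pcols[k] for k in PATIENT_COLUMNS if k not in _OPTIONAL_PATIENT_COLUMNS]
    for col in required:
        if col not in patients.columns:
            raise SchemaError(f"patient file lacks required column {col!r}")

    meals_by_patient: dict[str, list[MealIntake]] = {}
    if meals_path is not None:
        mcols = _resolve_schema(MEAL_COLUMNS, meal_schema)
        meals = pd.read_csv(meals_path, dtype=str, keep_default_na=False)
        for col in mcols.values():
            if col not in meals.columns:
                raise SchemaError(f"meal file lacks required column {col!r}")
        for i, row in enumerate(meals.itertuples(index=False)):
            get = lambda key: getattr(row, mcols[key])
            meal = MealIntake(
                date=_parse_date(get("date"), i, "meal date"),
                slot=str(get("slot")).strip(),
                principal_score=_parse_int(get("principal_score"), i, "principal_score"),
                side_score=_parse_int(get("side_score"), i, "side_score"),
            )
            meals_by_patient.setdefault(str(get("patient_id")), []).append(meal)

    cohort: list[PatientRecord] = []
    for i, row in patients.iterrows():
        get = lambda key: row[pcols[key]] if pcols[key] in patients.columns else ""
        pid = str(get("patient_id"))
        adm_date = _parse_date(get("adm_date"), i, "admission date")
        prior_w = get("prior_weight_kg")
        history = WeightHistory(
            admission_weight=_parse_float(get("adm_weight_kg"), i, "admission weight"),
            admission_date=adm_date,
            prior_weight=None if _is_missing(prior_w) else _parse_float(prior_w, i, "prior weight"),
            prior_weight_date=None
            if _is_missing(get("prior_weight_date"))
            else _parse_date(get("prior_weight_date"), i, "prior weight date"),
        )
        mna_values = {f: get(c) for c, f in _MNA_FIELDS.items()}
        if all(_is_missing(v) for v in mna_values.values()):
            mna = None
        elif any(_is_missing(v) for v in mna_values.values()):
            raise RowParseError(i, "MNA-SF interview is partially filled")
        else:
            mna = MnaInterview(**{f: str(v).strip() for f, v in mna_values.items()})
        alb = get("albumin_gdl")
        try:
            record = PatientRecord(
                patient_id=pid,
                age=_parse_int(get("age"), i, "age"),
                sex=str(get("sex")).strip(),
                diagnosis=str(get("diagnosis")).strip(),
                transferred_to_acute=_parse_bool(get("transferred"), i, "transferred"),
                height=_parse_float(get("height_m"), i, "height"),
                weight_history=history,
                serum_albumin=None if _is_missing(alb) else _parse_float(alb, i, "albumin"),
                decubitus=_parse_bool(get("decubitus"), i, "decubitus"),
                digestive_symptoms=_parse_bool(get("digestive"), i, "digestive"),
                tpn=_parse_bool(get("tpn"), i, "tpn"),
                meals=tuple(meals_by_patient.get(pid, ())),
            )
        except ValueError as exc:
            raise RowParseError(i, str(exc)) from exc
        if mna is not None:
            record = replace(record, mna=mna)
        cohort.append(record)
    return cohort


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_cohort_csv(
    cohort: Iterable[PatientRecord],
    patients_path,
    meals_path=None,
) -> None:
    """Write a cohort back to the two-file CSV layout read by
    :func:`read_cohort_csv` (round-trip safe)."""
    prow = []
    mrow = []
    for r in cohort:
        h = r.weight_history
        prow.append(
            {
                "patient_id": r.patient_id,
                "age": r.age,
                "sex": r.sex,
                "diagnosis": r.diagnosis,
                "transferred": _fmt(r.transferred_to_acute),
                "height_m": _fmt(r.height),
                "adm_weight_kg": _fmt(h.admission_weight),
                "adm_date": h.admission_date.isoformat(),
                "prior_weight_kg": _fmt(h.prior_weight),
                "prior_weight_date": "" if h.prior_weight_date is None else h.prior_weight_date.isoformat(),
                "albumin_gdl": _fmt(r.serum_albumin),
                "decubitus": _fmt(r.decubitus),
                "digestive": _fmt(r.digestive_symptoms),
                "tpn": _fmt(r.tpn),
                "mna_intake_decline": "" if r.mna is None else r.mna.intake_decline,
                "mna_weight_loss": "" if r.mna is None else r.mna.weight_loss_3mo,
                "mna_mobility": "" if r.mna is None else r.mna.mobility,
                "mna_stress": "" if r.mna is None else r.mna.stress,
                "mna_neuropsych": "" if r.mna is None else r.mna.neuropsych,
            }
        )
        for m in r.meals:
            mrow.append(
                {
                    "patient_id": r.patient_id,
                    "date": m.date.isoformat(),
                    "slot": m.slot,
                    "principal_score": m.principal_score,
                    "side_score": m.side_score,
                }
            )
    pd.DataFrame(prow, columns=list(PATIENT_COLUMNS)).to_csv(patients_path, index=False)
    if meals_path is not None:
        pd.DataFrame(mrow, columns=list(MEAL_COLUMNS)).to_csv(meals_path, index=False)


# ---------------------------------------------------------------------------
# Study-entry filters


@dataclass(frozen=True)
class Exclusion:
    """A record dropped by a filter, with machine-readable reasons."""

    record: PatientRecord
    reasons: tuple[str, ...]


def filter_eligible(
    cohort: Sequence[PatientRecord],
    min_age: int = 66,
    require_diagnosis: str | None = "cerebrovascular",
) -> tuple[list[PatientRecord], list[Exclusion]]:
    """Apply the study's entry criteria.

    Keeps patients aged ``min_age`` or older (the default 66 reads the
    "older than 65" entry criterion strictly; pass 65 for the inclusive
    reading), with the required diagnosis, not transferred back to an
    acute hospital.  Returns ``(kept, excluded)``; every input record
    lands in exactly one of the two.
    """
    kept: list[PatientRecord] = []
    excluded: list[Exclusion] = []
    for r in cohort:
        reasons = []
        if r.age < min_age:
            reasons.append("age")
        if require_diagnosis is not None and r.diagnosis != require_diagnosis:
            reasons.append("diagnosis")
        if r.transferred_to_acute:
            reasons.append("transfer")
        if reasons:
            excluded.append(Exclusion(r, tuple(reasons)))
        else:
            kept.append(r)
    return kept, excluded


#: field name -> predicate "is present on this record"
_COMPLETENESS_CHECKS = {
    "serum_albumin": lambda r: r.serum_albumin is not None,
    "prior_weight": lambda r: r.weight_history.prior_weight is not None,
    "meals": lambda r: len(r.meals) > 0,
    "mna": lambda r: r.mna is not None,
    "height": lambda r: True,  # structurally required; always present
}


def filter_complete(
    cohort: Sequence[PatientRecord],
    required_fields: Iterable[str] = ("serum_albumin", "prior_weight", "meals"),
) -> tuple[list[PatientRecord], list[Exclusion]]:
    """Drop records lacking any of ``required_fields``, logging which
    fields were missing for each exclusion."""
    checks = {}
    for f in required_fields:
        if f not in _COMPLETENESS_CHECKS:
            raise ValueError(f"unknown completeness field {f!r}")
        checks[f] = _COMPLETENESS_CHECKS[f]
    kept: list[PatientRecord] = []
    excluded: list[Exclusion] = []
    for r in cohort:
        missing = tuple(f for f, ok in checks.items() if not ok(r))
        if missing:
            excluded.append(Exclusion(r, missing))
        else:
            kept.append(r)
    return kept, excluded
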