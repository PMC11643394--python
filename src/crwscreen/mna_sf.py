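"""MNA-SF comparator: the six-item interview-based screen.

Five items come from a short interview (decline in food intake over the
last 3 months, weight loss over the last 3 months, mobility,
psychological stress / acute disease, neuropsychological problems); the
sixth is the BMI measured on the ward.  Each item maps to a small
integer score; totals are bucketed into malnutrition / at risk / good
nutrition, and for the concordance analysis the three levels collapse to
a binary malnutrition flag.

Two scoring maps are shipped.  ``paper_scoring_map()`` (the default)
scores "no decrease in food intake" as 3 points, giving a 15-point
scale.  ``standard_scoring_map()`` is the conventional instrument, where
that answer scores 2 and the maximum total is 14.  The binary cutoff is
likewise configurable between "total <= 7" (consistent with the 0-7
malnutrition bucket; the default) and the strict "total < 7".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

from .cohort import MnaInterview

__all__ = [
    "MnaScoringMap",
    "MnaResult",
    "paper_scoring_map",
    "standard_scoring_map",
    "bmi_item_score",
    "score_mna",
    "binary_group",
]

MALNUTRITION = "malnutrition"
AT_RISK = "at_risk"
GOOD = "good"
NON_MALNUTRITION = "non_malnutrition"

ITEM_NAMES = ("intake_decline", "weight_loss_3mo", "mobility", "stress", "neuropsych", "bmi")


@dataclass(frozen=True)
class MnaScoringMap:
    """Category-to-points tables for the six items plus the cutoffs.

    ``bmi_cutpoints`` (c1, c2, c3) bin BMI half-open on the left:
    <c1 -> 0, [c1, c2) -> 1, [c2, c3) -> 2, >=c3 -> 3.
    ``binary_rule`` is ``"lte"`` (malnourished when total <=
    ``malnutrition_max``) or ``"lt"`` (strictly below).
    """

    intake_decline: Mapping[str, int] = field(
        default_factory=lambda: {"severe": 0, "moderate": 1, "none": 3}
    )
    weight_loss_3mo: Mapping[str, int] = field(
        default_factory=lambda: {"gt3kg": 0, "unknown": 1, "1to3kg": 2, "none": 3}
    )
    mobility: Mapping[str, int] = field(
        default_factory=lambda: {"bed_or_chair": 0, "indoors": 1, "outdoors": 2}
    )
    stress: Mapping[str, int] = field(
        default_factory=lambda: {"under_stress": 0, "no_stress": 2}
    )
    neuropsych: Mapping[str, int] = field(
        default_factory=lambda: {"severe": 0, "moderate": 1, "none": 2}
    )
    bmi_cutpoints: tuple[float, float, float] = (19.0, 21.0, 23.0)
    malnutrition_max: int = 7
    at_risk_max: int = 11
    binary_rule: str = "lte"

    def __post_init__(self) -> None:
        for name in ("intake_decline", "weight_loss_3mo", "mobility", "stress", "neuropsych"):
            table = getattr(self, name)
            if any((not isinstance(v, int)) or v < 0 for v in table.values()):
                raise ValueError(f"{name} points must be nonnegative integers")
        c1, c2, c3 = self.bmi_cutpoints
        if not c1 < c2 < c3:
            raise ValueError("bmi_cutpoints must be strictly increasing")
        if not 0 <= self.malnutrition_max < self.at_risk_max:
            raise ValueError("cutoffs must satisfy 0 <= malnutrition_max < at_risk_max")
        if self.binary_rule not in ("lte", "lt"):
            raise ValueError("binary_rule must be 'lte' or 'lt'")

    def item_max(self, name: str) -> int:
        if name == "bmi":
            return 3
        return max(getattr(self, name).values())

    @property
    def total_max(self) -> int:
        return sum(self.item_max(n) for n in ITEM_NAMES)


def paper_scoring_map() -> MnaScoringMap:
    """15-point variant: "no decrease in food intake" scores 3."""
    return MnaScoringMap()


def standard_scoring_map() -> MnaScoringMap:
    """Conventional 14-point instrument: item 1 maxes at 2 points."""
    return MnaScoringMap(intake_decline={"severe": 0, "moderate": 1, "none": 2})


@dataclass(frozen=True)
class MnaResult:
    item_scores: tuple[int, int, int, int, int, int]  # ordered as ITEM_NAMES
    total: int
    category: str
    binary: str


def bmi_item_score(bmi: float, cutpoints: tuple[float, float, float] = (19.0, 21.0, 23.0)) -> int:
    """Score the BMI item on half-open bins."""
    if bmi <= 0:
        raise ValueError("bmi must be positive")
    c1, c2, c3 = cutpoints
    if bmi < c1:
        return 0
    if bmi < c2:
        return 1
    if bmi < c3:
        return 2
    return 3


def _categorise(total: int, scoring: MnaScoringMap) -> str:
    if total <= scoring.malnutrition_max:
        return MALNUTRITION
    if total <= scoring.at_risk_max:
        return AT_RISK
    return GOOD


def binary_group(total: int, scoring: MnaScoringMap = MnaScoringMap()) -> str:
    """Collapse the total to the binary malnutrition flag used in the
    concordance analysis."""
    if scoring.binary_rule == "lte":
        malnourished = total <= scoring.malnutrition_max
    else:
        malnourished = total < scoring.malnutrition_max
    return MALNUTRITION if malnourished else NON_MALNUTRITION


def score_mna(
    interview: MnaInterview,
    bmi: float,
    scoring: MnaScoringMap = MnaScoringMap(),
) -> MnaResult:
    """Score the interview plus the measured BMI into an :class:`MnaResult`."""
    if interview is None:
        raise ValueError("MNA-SF interview is missing")
    scores = tuple(
        getattr(scoring, name)[getattr(interview, name)]
        for name in ITEM_NAMES
        if name != "bmi"
    ) + (bmi_item_score(bmi, scoring.bmi_cutpoints),)
    total = sum(scores)
    return MnaResult(
        item_scores=scores,  # type: ignore[arg-type]
        total=total,
        category=_categorise(total, scoring),
        binary=binary_group(total, scoring),
    )
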