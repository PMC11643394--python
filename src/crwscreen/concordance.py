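"""Agreement between the two screens: 2x2 cross-tab, Cohen's kappa and
the four concordance groups.

Patients are cross-classified by the record-only screen (J-Method) and
the interview screen (MNA-SF).  Chance-corrected agreement is Cohen's
kappa,

    kappa = (p_o - p_e) / (1 - p_e),

with observed agreement p_o = (a + d)/n and chance agreement p_e from
the table marginals.  Strength bands: slight (0-0.20], fair (0.20-0.40],
moderate, substantial, almost perfect, with inclusive upper bounds;
negative kappa is below-chance.

Each patient also gets a concordance group: D (malnourished by both),
P-J (J-Method only), P-M (MNA-SF only), N (neither).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "CrossTab2x2",
    "KappaResult",
    "DegenerateTableError",
    "crosstab",
    "cohen_kappa",
    "kappa_from_cells",
    "assign_group",
    "group_counts",
    "GROUP_LABELS",
]

MALNUTRITION = "malnutrition"

GROUP_LABELS = ("D", "P-J", "P-M", "N")

_BANDS = (
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost_perfect"),
)


class DegenerateTableError(ValueError):
    """Kappa is undefined: empty table or degenerate marginals."""


@dataclass(frozen=True)
class CrossTab2x2:
    """Joint counts: a = both malnourished, b = J-Method only,
    c = MNA-SF only, d = neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def j_malnutrition(self) -> int:
        return self.a + self.b

    @property
    def mna_malnutrition(self) -> int:
        return self.a + self.c

    def proportions(self, ndigits: int = 1) -> dict[str, float]:
        """Marginal malnutrition percentages, rounded for display."""
        if self.n == 0:
            raise DegenerateTableError("empty table")
        return {
            "j_malnutrition_pct": round(100.0 * self.j_malnutrition / self.n, ndigits),
            "mna_malnutrition_pct": round(100.0 * self.mna_malnutrition / self.n, ndigits),
        }


@dataclass(frozen=True)
class KappaResult:
    p_observed: float
    p_expected: float
    kappa: float
    band: str
    se: float | None = None

    @property
    def ci95(self) -> tuple[float, float] | None:
        if self.se is None:
            return None
        return (self.kappa - 1.96 * self.se, self.kappa + 1.96 * self.se)


def crosstab(
    j_labels: Mapping[str, str],
    m_labels: Mapping[str, str],
) -> CrossTab2x2:
    """Cross-classify per-patient binary labels from the two screens.

    Both mappings are patient_id -> {malnutrition, non_malnutrition} and
    must cover the same non-empty patient set.
    """
    if set(j_labels) != set(m_labels):
        raise ValueError("J-Method and MNA-SF label maps cover different patients")
    if not j_labels:
        raise DegenerateTableError("empty patient set")
    a = b = c = d = 0
    for pid, j in j_labels.items():
        jm = j == MALNUTRITION
        mm = m_labels[pid] == MALNUTRITION
        if jm and mm:
            a += 1
        elif jm:
            b += 1
        elif mm:
            c += 1
        else:
            d += 1
    return CrossTab2x2(a, b, c, d)


def band_for(kappa: float) -> str:
    if kappa < 0:
        return "below_chance"
    for upper, name in _BANDS:
        if kappa <= upper:
            return name
    return "almost_perfect"


def kappa_from_cells(p_a: float, p_b: float, p_c: float, p_d: float) -> float:
    """Kappa from joint classification probabilities (or counts — any
    common scale divides out)."""
    n = p_a + p_b + p_c + p_d
    if n <= 0:
        raise DegenerateTableError("cells must have positive mass")
    po = (p_a + p_d) / n
    pe = ((p_a + p_b) * (p_a + p_c) + (p_c + p_d) * (p_b + p_d)) / n**2
    if pe >= 1.0:
        raise DegenerateTableError("degenerate marginals: chance agreement is 1")
    return (po - pe) / (1.0 - pe)


def cohen_kappa(tab: CrossTab2x2) -> KappaResult:
    """Cohen's kappa with the strength band and a large-sample standard
    error (the simple first-order approximation; not part of default
    reports)."""
    n = tab.n
    if n == 0:
        raise DegenerateTableError("empty table")
    po = (tab.a + tab.d) / n
    pe = ((tab.a + tab.b) * (tab.a + tab.c) + (tab.c + tab.d) * (tab.b + tab.d)) / n**2
    if pe >= 1.0:
        raise DegenerateTableError("degenerate marginals: chance agreement is 1")
    kappa = (po - pe) / (1.0 - pe)
    se = math.sqrt(po * (1.0 - po) / n) / (1.0 - pe)
    return KappaResult(p_observed=po, p_expected=pe, kappa=kappa, band=band_for(kappa), se=se)


def assign_group(j_label: str, m_label: str) -> str:
    """Concordance group of one patient from the two binary labels."""
    jm = j_label == MALNUTRITION
    mm = m_label == MALNUTRITION
    if jm and mm:
        return "D"
    if jm:
        return "P-J"
    if mm:
        return "P-M"
    return "N"


def group_counts(assignments: Sequence[str] | Mapping[str, str]) -> dict[str, dict[str, float]]:
    """Counts and percentage shares of the four concordance groups.

    ``assignments`` is either a sequence of labels or a patient_id ->
    label mapping.  Percentages are against the full n, rounded to one
    decimal for display.
    """
    labels = list(assignments.values()) if isinstance(assignments, Mapping) else list(assignments)
    bad = set(labels) - set(GROUP_LABELS)
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    n = len(labels)
    out = {}
    for g in GROUP_LABELS:
        count = labels.count(g)
        out[g] = {"count": count, "pct": round(100.0 * count / n, 1) if n else 0.0}
    return out
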