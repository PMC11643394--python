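"""End-to-end orchestration: filters, both screens, concordance, group
statistics, and a serialisable run report."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from typing import Sequence

import pandas as pd

from . import cohort as ch
from . import concordance as cc
from . import group_stats as gs
from . import jmethod as jm
from . import mna_sf

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "screen_cohort"]

log = logging.getLogger("crwscreen")

#: display order of the food-intake-decline interview categories
_DECLINE_CATEGORIES = ("none", "moderate", "severe")


@dataclass(frozen=True)
class PipelineConfig:
    """Every threshold and policy of a run, in one auditable place."""

    jmethod: jm.JMethodConfig = field(default_factory=jm.JMethodConfig)
    mna_map: mna_sf.MnaScoringMap = field(default_factory=mna_sf.MnaScoringMap)
    min_age: int = 66
    require_diagnosis: str | None = "cerebrovascular"
    required_fields: tuple[str, ...] = ("serum_albumin", "prior_weight", "meals")
    alpha: float = 0.05
    jmethod_only: bool = False


@dataclass
class RunReport:
    """Everything a run produces: cohort flow, per-screen counts,
    agreement, group statistics.  ``flow`` counts are nonincreasing
    along the filter chain and every input patient is accounted for in
    either the analyzed set or an exclusion."""

    flow: dict
    exclusions: list
    j_counts: dict
    classified: pd.DataFrame
    mna_counts: dict | None = None
    crosstab: cc.CrossTab2x2 | None = None
    kappa: cc.KappaResult | None = None
    group_counts: dict | None = None
    summaries: list = field(default_factory=list)
    summary_table: pd.DataFrame | None = None
    intake_decline_table: pd.DataFrame | None = None
    intake_decline_p: float | None = None
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        """JSON-ready view (DataFrames as records, dataclasses as dicts)."""
        out = {
            "flow": self.flow,
            "exclusions": self.exclusions,
            "j_counts": self.j_counts,
            "mna_counts": self.mna_counts,
            "warnings": self.warnings,
        }
        if self.crosstab is not None:
            out["crosstab"] = asdict(self.crosstab)
            out["marginals"] = self.crosstab.proportions()
        if self.kappa is not None:
            out["kappa"] = {
                "p_observed": self.kappa.p_observed,
                "p_expected": self.kappa.p_expected,
                "kappa": self.kappa.kappa,
                "kappa_display": round(self.kappa.kappa, 2),
                "band": self.kappa.band,
            }
        if self.group_counts is not None:
            out["group_counts"] = self.group_counts
        if self.summary_table is not None:
            out["summary_table"] = self.summary_table.to_dict(orient="records")
        if self.intake_decline_table is not None:
            out["intake_decline"] = {
                "table": self.intake_decline_table.reset_index(names="group").to_dict(orient="records"),
                "p": self.intake_decline_p,
            }
        return out


def screen_cohort(
    cohort: Sequence[ch.PatientRecord],
    config: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Score every record with both screens; one row per patient with
    the intermediate quantities, flags and labels."""
    rows = []
    for r in cohort:
        res = jm.screen_jmethod(r, config.jmethod)
        row = {
            "patient_id": r.patient_id,
            "weekly_weight_change_pct": res.weekly_weight_change_pct,
            "mean_intake_pct": res.mean_intake_pct,
            "mean_principal_pct": res.mean_principal_pct,
            "mean_side_pct": res.mean_side_pct,
            "bmi": res.bmi,
            **{f"crit_{k}": v for k, v in res.criteria.items()},
            "j_class": res.classification,
        }
        if not config.jmethod_only and r.mna is not None:
            m = mna_sf.score_mna(r.mna, res.bmi, config.mna_map)
            row.update(mna_total=m.total, mna_category=m.category, mna_class=m.binary)
        else:
            row.update(mna_total=None, mna_category=None, mna_class=None)
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    cohort: Sequence[ch.PatientRecord],
    config: PipelineConfig = PipelineConfig(),
) -> RunReport:
    """Filter, screen, cross-classify and compare a cohort.

    Deterministic for fixed inputs and config.  With ``jmethod_only``
    (or when no record carries an interview) the concordance and
    group-comparison sections are omitted.
    """
    n_input = len(cohort)
    eligible, excl_elig = ch.filter_eligible(cohort, config.min_age, config.require_diagnosis)
    required = config.required_fields
    if not config.jmethod_only and any(r.mna is not None for r in eligible):
        required = tuple(dict.fromkeys((*required, "mna")))
    complete, excl_comp = ch.filter_complete(eligible, required)
    exclusions = [
        {"patient_id": e.record.patient_id, "stage": stage, "reasons": list(e.reasons)}
        for stage, batch in (("eligibility", excl_elig), ("completeness", excl_comp))
        for e in batch
    ]
    for e in exclusions:
        log.info("excluded %(patient_id)s at %(stage)s: %(reasons)s", e)
    flow = {
        "input": n_input,
        "after_eligibility": len(eligible),
        "after_completeness": len(complete),
        "analyzed": len(complete),
    }

    report = RunReport(flow=flow, exclusions=exclusions, j_counts={}, classified=pd.DataFrame())
    if not complete:
        report.warnings.append("no patients left after filtering; statistics skipped")
        return report

    classified = screen_cohort(complete, config)
    report.classified = classified
    report.j_counts = classified["j_class"].value_counts().to_dict()

    have_mna = classified["mna_class"].notna()
    if config.jmethod_only or not have_mna.all():
        if not config.jmethod_only:
            report.warnings.append("records without MNA-SF interview; concordance skipped")
        return report

    report.mna_counts = classified["mna_class"].value_counts().to_dict()
    j_labels = dict(zip(classified["patient_id"], classified["j_class"]))
    m_labels = dict(zip(classified["patient_id"], classified["mna_class"]))
    tab = cc.crosstab(j_labels, m_labels)
    report.crosstab = tab
    report.kappa = cc.cohen_kappa(tab)
    groups = {pid: cc.assign_group(j_labels[pid], m_labels[pid]) for pid in j_labels}
    report.group_counts = cc.group_counts(groups)
    classified["group"] = classified["patient_id"].map(groups)

    by_id = {r.patient_id: r for r in complete}
    present = [g for g in cc.GROUP_LABELS if (classified["group"] == g).sum() >= 2]
    if len(present) >= 2:
        variables = {
            "age": lambda pid: by_id[pid].age,
            "bmi": None,
            "albumin": lambda pid: by_id[pid].serum_albumin,
            "principal_intake_pct": None,
            "side_intake_pct": None,
        }
        columns = {
            "bmi": "bmi",
            "principal_intake_pct": "mean_principal_pct",
            "side_intake_pct": "mean_side_pct",
        }
        for name, getter in variables.items():
            samples = {}
            for g in present:
                ids = classified.loc[classified["group"] == g, "patient_id"]
                if getter is not None:
                    samples[g] = [getter(pid) for pid in ids]
                else:
                    col = columns[name]
                    samples[g] = classified.loc[classified["group"] == g, col].tolist()
            try:
                report.summaries.append(gs.compare_numeric(samples, config.alpha, variable=name))
            except ValueError as exc:
                report.warnings.append(f"comparison of {name} skipped: {exc}")
        report.summary_table = gs.format_summary_table(report.summaries)

        decline = {
            g: [
                by_id[pid].mna.intake_decline
                for pid in classified.loc[classified["group"] == g, "patient_id"]
            ]
            for g in present
        }
        report.intake_decline_table = gs.category_table(decline, _DECLINE_CATEGORIES)
        counts = report.intake_decline_table[[f"{c}_count" for c in _DECLINE_CATEGORIES]]
        try:
            report.intake_decline_p = gs.compare_categorical(counts.to_numpy())
        except ValueError as exc:
            report.warnings.append(f"intake-decline test skipped: {exc}")
    else:
        report.warnings.append("fewer than 2 populated concordance groups; comparisons skipped")
    return report
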