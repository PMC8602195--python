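"""Outcome-concordance evaluation of laterality decisions.

Decisions are scored against the operated side of patients who underwent
resection alone, split by 24-month Engel outcome (class 1 = seizure-free
vs class ≥2).  A decision matches when it points to the operated side
(definitive or weak, i.e. L/UL match a left resection); an indeterminate
decision (U) counts as eligible but non-matching; not-performed and failed
metrics are excluded.

Two report shapes are produced:

* per-metric concordance fractions (matched / eligible) with a
  side × decision cross-tabulation, and
* per-patient agreement percentages (matches over available metrics) with
  group means and a pooled two-sample t-test comparing Engel class 1
  against Engel class ≥2 patients.

Two published Engel-1 concordance cells (the multistructural classifier and
the diffusion uncertainty analysis) do not reconcile with a recount of the
published per-patient table; those metric names are carried in
``ConcordanceReport.discrepant_metrics`` and the recounted values reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import decisions as dec
from .cohort import MODALITIES, CohortTable, SubjectRecord

MATCH = "match"
MISMATCH = "mismatch"
INDETERMINATE = "indeterminate"

#: metrics whose published Engel-1 fraction is internally inconsistent with
#: a recount of the published per-patient decisions
DISCREPANT_METRICS = ("msa", "dti_uncertainty")

ENGEL_GROUPS = ("engel_1", "engel_2plus")


def match_decision(decision: str, side: str) -> str:
    """Score one decision against an operated side.

    Returns ``"match"``, ``"mismatch"`` or ``"indeterminate"`` (U).
    """
    dec.validate(decision)
    if side not in ("left", "right"):
        raise ValueError(f"operated side must be left/right, got {side!r}")
    pointed = dec.side_of(decision)
    if pointed is None:
        return INDETERMINATE
    return MATCH if pointed == side else MISMATCH


def _resected(record: SubjectRecord) -> bool:
    return (record.procedure == "resection"
            and record.operated_side in ("left", "right")
            and record.engel_1 is not None)


def _engel_group(record: SubjectRecord) -> str:
    return "engel_1" if record.engel_1 else "engel_2plus"


@dataclass
class ConcordanceCell:
    matched: int
    eligible: int

    @property
    def fraction(self) -> float | None:
        return self.matched / self.eligible if self.eligible else None


@dataclass
class ConcordanceReport:
    """Per metric × Engel group match fractions and cross-tabulations."""

    cells: dict[tuple[str, str], ConcordanceCell]
    crosstab: pd.DataFrame
    discrepant_metrics: tuple[str, ...] = DISCREPANT_METRICS

    def fraction(self, metric: str, group: str = "engel_1") -> float | None:
        return self.cells[(metric, group)].fraction

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (metric, group), cell in self.cells.items():
            rows.append({
                "metric": metric, "engel_group": group,
                "matched": cell.matched, "eligible": cell.eligible,
                "fraction": cell.fraction,
                "flagged_discrepant": (metric in self.discrepant_metrics
                                       and group == "engel_1"),
            })
        return pd.DataFrame(rows)


def concordance_table(cohort: CohortTable,
                      metrics: tuple[str, ...] = MODALITIES,
                      ) -> ConcordanceReport:
    """Match each metric's decisions against the operated side.

    Only patients treated by resection alone with a recorded 24-month
    outcome enter; eligibility per metric additionally requires a usable
    decision (U is eligible, not-performed/failed are not).
    """
    resected = [r for r in cohort if _resected(r)]
    cells: dict[tuple[str, str], ConcordanceCell] = {}
    xt_rows = []
    for metric in metrics:
        for group in ENGEL_GROUPS:
            cells[(metric, group)] = ConcordanceCell(0, 0)
    for r in resected:
        group = _engel_group(r)
        for metric in metrics:
            token = r.decision(metric)
            if token in (dec.MISSING, dec.FAILED):
                continue
            outcome = match_decision(token, r.operated_side)
            cell = cells[(metric, group)]
            cell.eligible += 1
            if outcome == MATCH:
                cell.matched += 1
            bucket = ("U" if outcome == INDETERMINATE else
                      "L&UL" if dec.side_of(token) == "left" else "R&UR")
            xt_rows.append({"metric": metric, "engel_group": group,
                            "operated_side": r.operated_side[0].upper(),
                            "decision": bucket})
    if xt_rows:
        xt = (pd.DataFrame(xt_rows)
              .value_counts(["metric", "engel_group", "operated_side",
                             "decision"])
              .unstack("decision", fill_value=0)
              .reindex(columns=["L&UL", "R&UR", "U"], fill_value=0))
    else:
        xt = pd.DataFrame(columns=["L&UL", "R&UR", "U"])
    return ConcordanceReport(cells=cells, crosstab=xt)


@dataclass
class PatientAgreement:
    subject_id: str
    engel_group: str
    n_metrics: int
    n_matches: int

    @property
    def percent(self) -> float:
        return 100.0 * self.n_matches / self.n_metrics

    @property
    def percent_rounded(self) -> int:
        """Integer percent, half-up (62.5 → 63) as tabulated."""
        return int(np.floor(self.percent + 0.5))


@dataclass
class AgreementReport:
    """Per-patient agreement with operated side, plus the group contrast."""

    patients: list[PatientAgreement]
    group_mean: dict[str, float] = field(default_factory=dict)
    group_sd: dict[str, float] = field(default_factory=dict)
    t_statistic: float = float("nan")
    p_value: float = float("nan")
    df: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"patient_id": p.subject_id, "engel_group": p.engel_group,
             "n_metrics": p.n_metrics, "agreement_percent": p.percent,
             "agreement_percent_rounded": p.percent_rounded}
            for p in self.patients])


def agreement_per_patient(cohort: CohortTable,
                          metrics: tuple[str, ...] = MODALITIES,
                          ) -> AgreementReport:
    """Percent of available metrics agreeing with the operated side.

    Per resected patient: matches / available metrics × 100, where all
    decision columns (multimodal included) count toward the denominator
    when usable and U counts against agreement.  Group means/SDs over the
    Engel-1 and Engel-≥2 patients are compared with a classical pooled
    two-sample t-test (two-sided) on the unrounded percentages.
    """
    patients = []
    for r in cohort:
        if not _resected(r):
            continue
        usable = [t for t in (r.decision(m) for m in metrics)
                  if t not in (dec.MISSING, dec.FAILED)]
        if not usable:
            continue
        n_match = sum(match_decision(t, r.operated_side) == MATCH
                      for t in usable)
        patients.append(PatientAgreement(
            subject_id=r.subject_id, engel_group=_engel_group(r),
            n_metrics=len(usable), n_matches=n_match))
    report = AgreementReport(patients=patients)
    groups = {g: np.array([p.percent for p in patients if p.engel_group == g])
              for g in ENGEL_GROUPS}
    for g, vals in groups.items():
        if vals.size:
            report.group_mean[g] = float(vals.mean())
            report.group_sd[g] = float(vals.std(ddof=1)) if vals.size > 1 \
                else float("nan")
    a, b = groups["engel_1"], groups["engel_2plus"]
    if a.size >= 2 and b.size >= 2:
        t, p = stats.ttest_ind(a, b, equal_var=True)
        report.t_statistic, report.p_value = float(t), float(p)
        report.df = a.size + b.size - 2
    return report
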