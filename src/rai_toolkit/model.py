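"""Model/Results interface over the scoring and staging pipeline.

:class:`RenalAnginaModel` is built from cohort data (in memory or from
the two-file CSV schema); :meth:`~RenalAnginaModel.fit` applies the
eligibility filters, resolves baselines, scores the renal angina index,
stages day-3 AKI and evaluates the diagnostic performance, returning a
:class:`RenalAnginaResults` carrying the per-patient table, the
comparison reports and a text ``summary()``.

The "model" here is a fixed clinical rule set rather than an estimated
one, so ``fit`` evaluates it against the cohort instead of optimising
parameters; the Results object is still the single artifact holding
estimates (rates, metrics, AUCs), their contingency tables, and
diagnostics such as the count of unassessable patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
from typing import Sequence

import pandas as pd

from .cohort import (
    CohortFilterReport,
    MeasurementSeries,
    PatientRecord,
    apply_eligibility_filters,
    load_cohort,
)
from .config import AnalysisConfig
from .diagnostics import DiagnosticReport, build_report, format_pct
from .kdigo import KDIGOAssessment, day3_outcome
from .physiology import resolve_baseline_scr
from .scoring import AssessmentError, RAIResult, compute_rai

logger = logging.getLogger(__name__)


class RenalAnginaModel:
    """Renal angina risk-stratification analysis of a PICU cohort."""

    def __init__(
        self,
        records: Sequence[PatientRecord],
        series: Sequence[MeasurementSeries],
        config: AnalysisConfig | None = None,
        apply_filters: bool = True,
    ):
        if len(records) != len(series):
            raise ValueError("records and series must be aligned")
        self.records = list(records)
        self.series = list(series)
        self.config = config or AnalysisConfig()
        self.apply_filters = apply_filters

    @classmethod
    def from_csv(
        cls,
        static_path,
        measurements_path,
        config: AnalysisConfig | None = None,
        scr_units: str = "mg/dL",
        apply_filters: bool = True,
    ) -> "RenalAnginaModel":
        records, series = load_cohort(static_path, measurements_path, scr_units)
        return cls(records, series, config, apply_filters)

    def fit(self) -> "RenalAnginaResults":
        config = self.config
        series_by_id = {s.patient_id: s for s in self.series}
        if self.apply_filters:
            eligible, filter_report = apply_eligibility_filters(self.records)
        else:
            eligible = self.records
            filter_report = CohortFilterReport(
                len(self.records), 0, 0, 0, 0, len(self.records)
            )

        kept_records: list[PatientRecord] = []
        kept_series: list[MeasurementSeries] = []
        baselines = []
        rai_results: list[RAIResult] = []
        assessments: list[KDIGOAssessment] = []
        unassessable: list[str] = []
        for rec in eligible:
            s = series_by_id[rec.patient_id]
            k = config.schwartz.k_for(rec.age_months, rec.sex)
            baseline = resolve_baseline_scr(
                rec.baseline_scr, rec.height_cm, k, config.baseline.assumed_ecrcl
            )
            try:
                rai = compute_rai(rec, s, baseline, config)
                kd = day3_outcome(rec, s, baseline, config)
            except AssessmentError as err:
                logger.warning("unassessable: %s", err)
                unassessable.append(rec.patient_id)
                continue
            kept_records.append(rec)
            kept_series.append(s)
            baselines.append(baseline)
            rai_results.append(rai)
            assessments.append(kd)

        reports = (
            build_report(
                kept_records, rai_results, assessments, baselines, kept_series, config
            )
            if kept_records
            else {}
        )
        return RenalAnginaResults(
            model=self,
            filter_report=filter_report,
            records=kept_records,
            rai_results=rai_results,
            assessments=assessments,
            unassessable=unassessable,
            reports=reports,
        )


@dataclass
class RenalAnginaResults:
    model: RenalAnginaModel
    filter_report: CohortFilterReport
    records: list[PatientRecord]
    rai_results: list[RAIResult]
    assessments: list[KDIGOAssessment]
    unassessable: list[str]
    reports: dict[str, DiagnosticReport] = field(default_factory=dict)

    @property
    def n_assessed(self) -> int:
        return len(self.records)

    def rai_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient_id": r.patient_id,
                    "risk_score": r.risk_score,
                    "injury_score": r.injury_score,
                    "injury_driver": r.injury_driver,
                    "ecrcl_decline_pct": r.ecrcl_decline_pct,
                    "fo_pct": r.fo_pct,
                    "rai": r.rai,
                    "ra_positive": r.ra_positive,
                    "assessment_time_h": r.assessment_time_h,
                }
                for r in self.rai_results
            ]
        )

    def kdigo_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient_id": a.patient_id,
                    "eval_day": a.eval_day,
                    "scr_stage": a.scr_stage,
                    "uop_stage": a.uop_stage,
                    "combined_stage": a.combined_stage,
                    "severe": a.severe,
                    "uop_available": a.uop_available,
                    "criteria_fired": ";".join(a.criteria_fired),
                }
                for a in self.assessments
            ]
        )

    def summary(self) -> str:
        fr = self.filter_report
        lines = [
            "Renal angina index analysis",
            "=" * 40,
            f"Identified encounters:    {fr.n_identified}",
            f"Eligible patients:        {fr.n_eligible}",
            f"  excluded (age):         {fr.n_excluded_age}",
            f"  excluded (CKD):         {fr.n_excluded_ckd}",
            f"  excluded (stay <72 h):  {fr.n_excluded_short_stay}",
            f"  excluded (no consent):  {fr.n_excluded_no_consent}",
            f"Assessed:                 {self.n_assessed}",
            f"Unassessable:             {len(self.unassessable)}",
        ]
        if self.n_assessed:
            n = self.n_assessed
            n_ra = sum(r.ra_positive for r in self.rai_results)
            n_aki = sum(a.combined_stage >= 1 for a in self.assessments)
            n_sev = sum(a.severe for a in self.assessments)
            lines += [
                "-" * 40,
                f"RA+ (RAI >= 8):           {n_ra} ({format_pct(100 * n_ra / n)}%)",
                f"Day 3 AKI (any stage):    {n_aki} ({format_pct(100 * n_aki / n)}%)",
                f"Severe day 3 AKI:         {n_sev} ({format_pct(100 * n_sev / n)}%)",
            ]
            perf = self.reports.get("predictor_performance")
            if perf is not None:
                lines += ["-" * 40, "Predictor performance (severe day 3 AKI):"]
                for name, m in perf.metrics.items():
                    lines.append(
                        f"  {name}: sens {format_pct(100 * m.sensitivity)}%, "
                        f"spec {format_pct(100 * m.specificity)}%, AUC {m.auc:.3f}"
                    )
        return "\n".join(lines)
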