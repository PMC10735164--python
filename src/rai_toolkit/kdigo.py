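"""AKI staging from creatinine and urine-output series.

Stages follow the study's operational rules:

* stage 1 — creatinine rise >= 0.3 mg/dL from an earlier value (or the
  resolved baseline) within 48 h, or urine output < 0.5 mL/kg/h sustained
  for 6 to <12 h;
* stage 2 — creatinine 2.0-2.9x baseline within the prior 7 days, or
  urine output < 0.5 mL/kg/h for more than 12 h;
* stage 3 — creatinine >= 3.0x baseline, creatinine > 4 mg/dL, Schwartz
  eCrCl < 35 mL/min/1.73 m^2, urine output < 0.3 mL/kg/h for 24 h, or
  anuria for more than 12 h.

Initiation of dialysis is an outcome variable here, *not* a stage-3
criterion.  The canonical 1.5-1.9x stage-1 ratio criterion is omitted by
default to match the rules as operationalised, and can be enabled via
``kdigo.canonical``.  Combined stage is the maximum of the creatinine and
urine axes; severe AKI is stage >= 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np

from .cohort import MeasurementSeries, PatientRecord
from .config import AnalysisConfig
from .physiology import BaselineResolution, schwartz_ecrcl

logger = logging.getLogger(__name__)

DELTA_SCR_MGDL = 0.3
DELTA_WINDOW_H = 48.0
SCR_ABSOLUTE_MGDL = 4.0
EGFR_FLOOR = 35.0


class StagingError(Exception):
    """The patient cannot be staged (no creatinine data)."""


@dataclass
class KDIGOAssessment:
    patient_id: str
    eval_day: int
    scr_stage: int
    uop_stage: int
    combined_stage: int
    severe: bool
    criteria_fired: list[str] = field(default_factory=list)
    uop_available: bool = True

    def __post_init__(self) -> None:
        if self.combined_stage != max(self.scr_stage, self.uop_stage):
            raise ValueError("combined_stage must be max of the two axes")
        if self.severe != (self.combined_stage >= 2):
            raise ValueError("severe must mirror combined_stage >= 2")
        if (len(self.criteria_fired) > 0) != (self.combined_stage >= 1):
            raise ValueError("criteria_fired nonempty iff staged >= 1")


def scr_stage(
    series: MeasurementSeries,
    baseline: BaselineResolution,
    eval_day: int,
    height_cm: float,
    k: float,
    canonical: bool = False,
) -> tuple[int, list[str]]:
    """Creatinine-axis stage over all values up to ``eval_day``.

    The 0.3 mg/dL delta criterion is checked between every pair of values
    no more than 48 h apart (the baseline acting as a value at admission);
    ratio criteria compare each value against the resolved baseline, all
    in-study days lying within 7 days of it.
    """
    horizon_h = eval_day * 24.0
    t_all, v_all = series.select("scr")
    mask = t_all <= horizon_h
    if not mask.any():
        raise StagingError(f"{series.patient_id}: no creatinine data by day {eval_day}")
    times = np.concatenate(([0.0], t_all[mask]))
    values = np.concatenate(([baseline.baseline_scr], v_all[mask]))

    fired: list[str] = []
    stage = 0
    # pairwise 48 h delta (reference earlier or simultaneous)
    dt = times[None, :] - times[:, None]
    dv = values[None, :] - values[:, None]
    if bool(np.any((dt >= 0) & (dt <= DELTA_WINDOW_H) & (dv >= DELTA_SCR_MGDL))):
        fired.append("delta_scr_48h")
        stage = max(stage, 1)

    ratios = values[1:] / baseline.baseline_scr
    if canonical and bool(np.any((ratios >= 1.5) & (ratios < 2.0))):
        fired.append("ratio_15x_7d")
        stage = max(stage, 1)
    if bool(np.any((ratios >= 2.0) & (ratios < 3.0))):
        fired.append("ratio_2x_7d")
        stage = max(stage, 2)
    if bool(np.any(ratios >= 3.0)):
        fired.append("ratio_3x")
        stage = 3
    if bool(np.any(values[1:] > SCR_ABSOLUTE_MGDL)):
        fired.append("scr_gt_4")
        stage = 3
    ecrcl = np.array([schwartz_ecrcl(height_cm, v, k) for v in values[1:]])
    if bool(np.any(ecrcl < EGFR_FLOOR)):
        fired.append("egfr_lt_35")
        stage = 3
    return stage, fired


def _hourly_runs(
    series: MeasurementSeries, weight_kg: float, horizon_h: float
) -> list[np.ndarray]:
    """Contiguous runs of hourly urine rates (mL/kg/h) before the horizon."""
    t, v = series.select("urine_output")
    mask = t < horizon_h
    if not mask.any():
        return []
    hours = np.floor(t[mask]).astype(int)
    rates: dict[int, float] = {}
    for h, vol in zip(hours, v[mask]):
        rates[h] = rates.get(h, 0.0) + vol / weight_kg
    runs: list[np.ndarray] = []
    current: list[float] = []
    prev_h: int | None = None
    for h in sorted(rates):
        if prev_h is not None and h != prev_h + 1:
            runs.append(np.asarray(current))
            current = []
        current.append(rates[h])
        prev_h = h
    if current:
        runs.append(np.asarray(current))
    return runs


def uop_stage(
    series: MeasurementSeries, weight_kg: float, eval_day: int
) -> tuple[int, list[str]]:
    """Urine-output-axis stage from the hourly series up to ``eval_day``.

    Window semantics at hourly resolution: stage 1 from any contiguous
    window of 6-11 h with mean rate < 0.5 mL/kg/h, stage 2 from any window
    longer than 12 h (>= 13 h) with mean < 0.5, stage 3 from any 24 h
    window with mean < 0.3 or any all-zero window longer than 12 h.
    Missing hours break window contiguity.  Returns stage 0 with no
    criteria if the series carries no urine data (creatinine-only
    staging; callers flag this).
    """
    if weight_kg <= 0:
        raise ValueError("weight_kg must be > 0")
    runs = _hourly_runs(series, weight_kg, eval_day * 24.0)
    fired: set[str] = set()
    stage = 0
    for run in runs:
        n = len(run)
        csum = np.concatenate(([0.0], np.cumsum(run)))
        for length in range(6, n + 1):
            means = (csum[length:] - csum[:-length]) / length
            if 6 <= length < 12 and bool(np.any(means < 0.5)):
                fired.add("uop_lt_05_6to12h")
                stage = max(stage, 1)
            if length >= 13 and bool(np.any(means < 0.5)):
                fired.add("uop_lt_05_gt12h")
                stage = max(stage, 2)
            if length >= 24 and bool(np.any(means < 0.3)):
                fired.add("uop_lt_03_24h")
                stage = 3
        # anuria: longest all-zero stretch must exceed 12 h
        zero = run == 0.0
        best = cur = 0
        for z in zero:
            cur = cur + 1 if z else 0
            best = max(best, cur)
        if best >= 13:
            fired.add("anuria_12h")
            stage = 3
    return stage, sorted(fired)


def day3_outcome(
    record: PatientRecord,
    series: MeasurementSeries,
    baseline: BaselineResolution,
    config: AnalysisConfig | None = None,
) -> KDIGOAssessment:
    """Primary-outcome staging at the configured evaluation day.

    Combined stage is the maximum of the two axes; dialysis initiation is
    recorded separately as an outcome and never forces stage 3.  Absent
    urine data degrades to creatinine-only staging with a logged flag.
    """
    config = config or AnalysisConfig()
    day = config.kdigo.eval_day
    k = config.schwartz.k_for(record.age_months, record.sex)
    s_stage, s_fired = scr_stage(
        series, baseline, day, record.height_cm, k, config.kdigo.canonical
    )
    u_stage, u_fired = uop_stage(series, record.admission_weight_kg, day)
    uop_available = bool(np.any(series.kinds == "urine_output"))
    if not uop_available:
        logger.info("%s: uop_unavailable, creatinine-only staging", record.patient_id)
    combined = max(s_stage, u_stage)
    return KDIGOAssessment(
        patient_id=record.patient_id,
        eval_day=day,
        scr_stage=s_stage,
        uop_stage=u_stage,
        combined_stage=combined,
        severe=combined >= 2,
        criteria_fired=s_fired + u_fired,
        uop_available=uop_available,
    )
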