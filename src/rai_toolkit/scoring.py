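"""Renal angina index (RAI) computation.

The RAI is the product of a risk stratum and an injury tier, assessed
within the first 8-12 hours of PICU admission:

* risk: 1 for ICU admission alone, 3 for solid-organ or stem-cell
  transplant, 5 for mechanical ventilation and/or vasoactive support
  (highest applicable stratum wins);
* injury: the worse of the percent decline in estimated creatinine
  clearance from baseline and the percent fluid overload, tiered
  1/2/4/8.

Scores range 1-40; renal angina is fulfilled (RA+) at RAI >= 8.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np

from .cohort import MeasurementSeries, PatientRecord
from .config import AnalysisConfig
from .physiology import BaselineResolution, percent_fluid_overload, schwartz_ecrcl

logger = logging.getLogger(__name__)

RISK_SCORES = (1, 3, 5)
INJURY_SCORES = (1, 2, 4, 8)
RA_THRESHOLD = 8
ATTAINABLE_RAI = tuple(sorted({r * i for r in RISK_SCORES for i in INJURY_SCORES}))


class AssessmentError(Exception):
    """The patient cannot be scored (no creatinine in the window)."""


@dataclass
class RAIResult:
    patient_id: str
    risk_score: int
    injury_score: int
    injury_driver: str  # "ecrcl_decline" | "fluid_overload" | "tie"
    ecrcl_decline_pct: float
    fo_pct: float
    rai: int
    ra_positive: bool
    assessment_time_h: float

    def __post_init__(self) -> None:
        if self.risk_score not in RISK_SCORES:
            raise ValueError(f"invalid risk score {self.risk_score}")
        if self.injury_score not in INJURY_SCORES:
            raise ValueError(f"invalid injury score {self.injury_score}")
        if self.rai != self.risk_score * self.injury_score:
            raise ValueError("rai must equal risk x injury")
        if self.ra_positive != (self.rai >= RA_THRESHOLD):
            raise ValueError("ra_positive must mirror rai >= 8")


def risk_score(
    icu_admitted: bool, transplant: bool, vent_or_inotrope: bool
) -> int:
    """Risk stratum: 5 ventilation/vasoactive, 3 transplant, 1 ICU alone."""
    if not icu_admitted:
        raise ValueError("risk score is defined for ICU admissions only")
    if vent_or_inotrope:
        return 5
    if transplant:
        return 3
    return 1


def _decline_tier(decline_pct: float) -> int:
    # "no change" (<= 0) tier 1; bands half-open, lower bound inclusive
    if decline_pct <= 0:
        return 1
    if decline_pct < 25:
        return 2
    if decline_pct < 50:
        return 4
    return 8


def _fo_tier(fo_pct: float) -> int:
    if fo_pct <= 5:
        return 1
    if fo_pct < 10:
        return 2
    if fo_pct < 15:
        return 4
    return 8


def injury_tier(ecrcl_decline_pct: float, fo_pct: float) -> tuple[int, str]:
    """Injury tier (1/2/4/8) and which signal attained it.

    The worse of the clearance-decline tier and fluid-overload tier wins;
    equal tiers are reported as a tie.
    """
    if not (np.isfinite(ecrcl_decline_pct) and np.isfinite(fo_pct)):
        raise ValueError("injury signals must be finite")
    d = _decline_tier(ecrcl_decline_pct)
    f = _fo_tier(fo_pct)
    if d > f:
        return d, "ecrcl_decline"
    if f > d:
        return f, "fluid_overload"
    return d, "tie"


def compute_rai(
    record: PatientRecord,
    series: MeasurementSeries,
    baseline: BaselineResolution,
    config: AnalysisConfig | None = None,
) -> RAIResult:
    """Score one patient at the configured assessment window.

    Uses the latest creatinine in [0, window] for the clearance decline
    versus baseline, the cumulative fluid balance over the same window,
    and support flags active within the window (or at its end, per
    config).  Raises :class:`AssessmentError` when no creatinine value
    falls inside the window.
    """
    config = config or AnalysisConfig()
    window = config.rai.window_h
    k = config.schwartz.k_for(record.age_months, record.sex)

    scr_t, scr_v = series.select("scr")
    in_window = scr_t <= window
    if not in_window.any():
        raise AssessmentError(
            f"{record.patient_id}: no creatinine value within [0, {window}] h"
        )
    idx = int(np.flatnonzero(in_window)[-1])
    scr_now = float(scr_v[idx])

    ecrcl_now = schwartz_ecrcl(record.height_cm, scr_now, k)
    ecrcl_base = schwartz_ecrcl(record.height_cm, baseline.baseline_scr, k)
    decline_pct = (1.0 - ecrcl_now / ecrcl_base) * 100.0

    fo_pct = percent_fluid_overload(series, record.admission_weight_kg, window).percent_fo

    vent = series.support_active("ventilation", window, config.rai.support_mode)
    ino = series.support_active("inotrope", window, config.rai.support_mode)

    risk = risk_score(True, record.transplant_flag, vent or ino)
    injury, driver = injury_tier(decline_pct, fo_pct)
    rai = risk * injury
    return RAIResult(
        patient_id=record.patient_id,
        risk_score=risk,
        injury_score=injury,
        injury_driver=driver,
        ecrcl_decline_pct=decline_pct,
        fo_pct=fo_pct,
        rai=rai,
        ra_positive=rai >= RA_THRESHOLD,
        assessment_time_h=window,
    )
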