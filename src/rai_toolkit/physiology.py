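"""Pediatric renal physiology estimates.

Schwartz estimated creatinine clearance, baseline creatinine resolution
and percent fluid overload (%FO).  The Schwartz form is

    eCrCl = k x height(cm) / SCr(mg/dL)   [mL/min/1.73 m^2]

with k a configurable constant (bedside value 0.413 by default).  The
baseline creatinine is the lowest pre-admission value when one exists;
otherwise it is back-calculated from an assumed normal clearance
(default 120 mL/min/1.73 m^2), the convention of the renal-angina
literature.  %FO is the standard ICU cumulative fluid balance:

    %FO = (sum intake - sum output) / (admission weight in kg x 1000) x 100

treating all fluids as density 1 g/mL.  Negative balances are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np

from .cohort import MeasurementSeries

logger = logging.getLogger(__name__)

DEFAULT_SCHWARTZ_K = 0.413
DEFAULT_ASSUMED_ECRCL = 120.0


@dataclass
class BaselineResolution:
    baseline_scr: float  # mg/dL
    source: str  # "historical_minimum" | "back_calculated"
    assumed_baseline_ecrcl: float | None = None

    def __post_init__(self) -> None:
        if self.baseline_scr <= 0:
            raise ValueError("baseline_scr must be > 0")
        if (self.source == "back_calculated") != (
            self.assumed_baseline_ecrcl is not None
        ):
            raise ValueError(
                "assumed_baseline_ecrcl is set iff source is back_calculated"
            )


@dataclass
class FluidBalance:
    window_start_h: float
    window_end_h: float
    total_in_ml: float
    total_out_ml: float
    percent_fo: float

    def __post_init__(self) -> None:
        if self.window_end_h <= self.window_start_h:
            raise ValueError("window_end_h must exceed window_start_h")
        if self.total_in_ml < 0 or self.total_out_ml < 0:
            raise ValueError("fluid totals must be >= 0")


def schwartz_ecrcl(height_cm: float, scr_mgdl: float, k: float = DEFAULT_SCHWARTZ_K) -> float:
    """Estimated creatinine clearance, mL/min/1.73 m^2."""
    if height_cm <= 0:
        raise ValueError("height_cm must be > 0")
    if scr_mgdl <= 0:
        raise ValueError("scr_mgdl must be > 0")
    if k <= 0:
        raise ValueError("k must be > 0")
    return k * height_cm / scr_mgdl


def resolve_baseline_scr(
    historical_min_scr: float | None,
    height_cm: float,
    k: float = DEFAULT_SCHWARTZ_K,
    assumed_ecrcl: float = DEFAULT_ASSUMED_ECRCL,
) -> BaselineResolution:
    """Resolve the baseline creatinine.

    The lowest creatinine of the 3 months before admission is used when
    available; otherwise the baseline is back-calculated by inverting the
    Schwartz equation at an assumed normal clearance.
    """
    if assumed_ecrcl <= 0:
        raise ValueError("assumed_ecrcl must be > 0")
    if historical_min_scr is not None:
        if historical_min_scr <= 0:
            raise ValueError("historical_min_scr must be > 0")
        return BaselineResolution(historical_min_scr, "historical_minimum")
    baseline = schwartz_ecrcl(height_cm, 1.0, k) / assumed_ecrcl  # k*h/ecrcl
    logger.debug(
        "baseline creatinine back-calculated from assumed eCrCl %.1f -> %.4f mg/dL",
        assumed_ecrcl,
        baseline,
    )
    return BaselineResolution(baseline, "back_calculated", assumed_ecrcl)


def percent_fluid_overload(
    series: MeasurementSeries,
    admission_weight_kg: float,
    window_end_h: float,
    window_start_h: float = 0.0,
) -> FluidBalance:
    """Cumulative %FO over [window_start_h, window_end_h]."""
    if admission_weight_kg <= 0:
        raise ValueError("admission_weight_kg must be > 0")
    if window_end_h <= window_start_h:
        raise ValueError("window_end_h must exceed window_start_h")
    in_t, in_v = series.select("fluid_in")
    out_t, out_v = series.select("fluid_out")
    in_mask = (in_t >= window_start_h) & (in_t <= window_end_h)
    out_mask = (out_t >= window_start_h) & (out_t <= window_end_h)
    if not in_mask.any() and not out_mask.any():
        logger.warning(
            "%s: no fluid entries in [%g, %g] h; %%FO set to 0",
            series.patient_id,
            window_start_h,
            window_end_h,
        )
        return FluidBalance(window_start_h, window_end_h, 0.0, 0.0, 0.0)
    total_in = float(np.sum(in_v[in_mask]))
    total_out = float(np.sum(out_v[out_mask]))
    pct = (total_in - total_out) / (admission_weight_kg * 1000.0) * 100.0
    return FluidBalance(window_start_h, window_end_h, total_in, total_out, pct)
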