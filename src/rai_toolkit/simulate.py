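"""Seedable synthetic PICU cohort generator.

Real pediatric ICU cohorts of this kind are not publicly deposited, so
every pipeline stage is exercised against synthetic cohorts whose
*conditional outcome structure* matches the published cohort: the
renal-angina positivity rate, the day-3 AKI and severe-AKI rates within
each renal-angina stratum, support use, dialysis, mortality and length
of stay.

Generation works *backwards* from the scoring rules: each patient first
receives latent labels (renal-angina status, intended day-3 KDIGO
stage), then a creatinine trajectory, hourly urine output and fluid
balance are constructed so that running the scorer and stager on the
generated series reproduces those labels exactly.  This gives the test
suite ground truth to validate against; a ``label_noise`` parameter
(default 0) lets users break the perfect correspondence.

Physiologic distributions (baseline creatinine by age, height/weight
growth curves, urine rates) are documented conventions, not fitted
models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import math

import numpy as np
import pandas as pd

from .cohort import DIAGNOSES, MeasurementSeries, PatientRecord
from .config import AnalysisConfig
from .physiology import resolve_baseline_scr

# diagnosis mix follows the published admission-diagnosis frequencies;
# order matches cohort.DIAGNOSES
DEFAULT_DIAGNOSIS_MIX = (0.108, 0.117, 0.108, 0.105, 0.099, 0.108, 0.237, 0.080, 0.038)


class ConfigValidationError(ValueError):
    pass


@dataclass
class CohortConfig:
    n_patients: int = 446
    seed: int = 0
    # renal-angina stratum prevalences and conditional outcome rates
    p_ra_positive: float = 0.199
    p_aki_given_ra_pos: float = 0.741
    p_aki_given_ra_neg: float = 0.106
    p_severe_given_ra_pos: float = 0.606
    p_severe_given_ra_neg: float = 0.042
    p_stage3_given_severe_ra_pos: float = 23.0 / 54.0
    p_stage3_given_severe_ra_neg: float = 0.0
    p_vent_given_ra_pos: float = 0.617
    p_vent_given_ra_neg: float = 0.184
    p_inotrope_given_ra_pos: float = 0.617
    p_inotrope_given_ra_neg: float = 0.137
    p_transplant: float = 0.02
    p_dialysis_given_ra_pos: float = 0.213
    p_dialysis_given_ra_neg: float = 0.011
    p_death_given_ra_pos: float = 0.314
    p_death_given_ra_neg: float = 0.028
    los_mean_ra_pos: float = 11.1
    los_sd_ra_pos: float = 3.5
    los_mean_ra_neg: float = 5.5
    los_sd_ra_neg: float = 2.1
    diagnosis_mix: tuple = DEFAULT_DIAGNOSIS_MIX
    sex_male_frac: float = 0.586
    age_months_range: tuple = (2.0, 168.0)
    # baseline creatinine: age-interpolated lognormal medians (mg/dL)
    baseline_scr_median_infant: float = 0.3
    baseline_scr_median_adolescent: float = 0.7
    baseline_scr_log_sd: float = 0.15
    p_historical_baseline: float = 0.4
    # injury route mixture for RA+ construction: clearance / fluid / both
    injury_route_mix: tuple = (0.5, 0.3, 0.2)
    label_noise: float = 0.0
    # illness severity covariate (given input, not computed)
    prism_mean: float = 12.0
    prism_sd: float = 6.0
    prism_aki_shift: float = 2.0
    prism_severe_shift: float = 5.0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigValidationError("n_patients must be >= 0")
        props = {
            k: v
            for k, v in asdict(self).items()
            if k.startswith("p_") or k == "sex_male_frac" or k == "label_noise"
        }
        for name, v in props.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigValidationError(f"{name}={v} outside [0, 1]")
        if abs(sum(self.diagnosis_mix) - 1.0) > 1e-9 or len(self.diagnosis_mix) != len(
            DIAGNOSES
        ):
            raise ConfigValidationError(
                "diagnosis_mix must have 9 entries summing to 1"
            )
        if abs(sum(self.injury_route_mix) - 1.0) > 1e-9:
            raise ConfigValidationError("injury_route_mix must sum to 1")
        if self.p_severe_given_ra_pos > self.p_aki_given_ra_pos:
            raise ConfigValidationError("p_severe_given_ra_pos exceeds p_aki_given_ra_pos")
        if self.p_severe_given_ra_neg > self.p_aki_given_ra_neg:
            raise ConfigValidationError("p_severe_given_ra_neg exceeds p_aki_given_ra_neg")
        if self.los_sd_ra_pos <= 0 or self.los_sd_ra_neg <= 0:
            raise ConfigValidationError("LOS standard deviations must be > 0")


def default_config() -> CohortConfig:
    """Paper-calibrated defaults (Table 3 conditional structure)."""
    return CohortConfig()


# ---------------------------------------------------------------------------
# demographic conventions


def _height_cm(age_months: float, rng: np.random.Generator) -> float:
    if age_months < 12:
        h = 50.0 + 2.1 * age_months
    else:
        h = 75.0 + 6.0 * (age_months - 12.0) / 12.0
    return max(45.0, h + rng.normal(0.0, 3.0))


def _weight_kg(age_months: float, rng: np.random.Generator) -> float:
    if age_months < 12:
        w = 3.5 + 0.5 * age_months
    else:
        w = 2.0 * (age_months / 12.0) + 9.0
    return max(2.5, w * math.exp(rng.normal(0.0, 0.1)))


def _truncnorm_min(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    for _ in range(200):
        x = rng.normal(mean, sd)
        if x >= lo:
            return x
    return lo


# ---------------------------------------------------------------------------
# injury construction

_MIN_TIER_FOR_RA = {1: 8, 3: 4, 5: 2}
_MAX_TIER_FOR_NOT_RA = {1: 4, 3: 2, 5: 1}
_DECLINE_BANDS = {2: (3.0, 22.0), 4: (25.0, 47.0), 8: (50.0, 65.0)}
_FO_BANDS = {2: (5.5, 9.5), 4: (10.2, 14.5), 8: (15.5, 25.0)}


def _decline_upper_bound(
    tier: int, intended_stage: int, b: float, scr_ceiling: float
) -> float:
    """Largest clearance-decline % (within the tier band) that does not
    push the assessment-window creatinine past the intended KDIGO stage."""
    lo, hi = _DECLINE_BANDS[tier]
    if intended_stage < 3:
        # window creatinine must stay under the eGFR-35 / 4 mg/dL ceilings
        limit = min(4.0, scr_ceiling) * 0.97
        hi = min(hi, 100.0 * (1.0 - b / limit))
    if intended_stage < 2:
        hi = min(hi, 49.0)  # ratio must stay < 2
    if intended_stage < 1:
        hi = min(hi, 30.0 / (b + 0.3) - 0.5)  # 48 h delta must stay < 0.3
    return hi if hi > lo else float("nan")


def _plan_injury(
    rng: np.random.Generator,
    tier: int,
    route_mix: tuple,
    b: float,
    scr_ceiling: float,
    intended_stage: int,
) -> tuple[float, float, str]:
    """Pick (decline %, FO %) hitting the target tier without breaking the
    intended KDIGO stage.  Falls back to the fluid route when the required
    creatinine elevation is physiologically incompatible with the stage."""
    d_neutral = rng.uniform(-5.0, 0.0)
    f_neutral = rng.uniform(0.0, 4.0)
    if tier == 1:
        return d_neutral, f_neutral, "none"
    route = rng.choice(("ecrcl", "fo", "both"), p=route_mix)
    d, f = d_neutral, f_neutral
    if route in ("ecrcl", "both"):
        lo, _ = _DECLINE_BANDS[tier]
        hi = _decline_upper_bound(tier, intended_stage, b, scr_ceiling)
        if math.isnan(hi):
            route = "fo"
        else:
            d = rng.uniform(lo, hi)
    if route in ("fo", "both"):
        f = rng.uniform(*_FO_BANDS[tier])
    return d, f, route


# ---------------------------------------------------------------------------
# per-patient series construction


def _build_scr_trajectory(
    rng: np.random.Generator,
    b: float,
    d: float,
    window_h: float,
    intended_stage: int,
    scr_ceiling: float,
) -> tuple[list[tuple[float, float]], str]:
    """Daily creatinine values (plus the assessment-window value) hitting
    the intended day-3 stage.  Returns [(time_h, scr)] and the day-3 route
    ('creat', 'urine' meaning the urine axis must carry the stage, or
    'none')."""
    t_inj = 0.8 * window_h
    scr_inj = b / (1.0 - d / 100.0)
    points = [(0.0, b), (t_inj, scr_inj)]

    def decay(frac: float) -> float:
        return b + (scr_inj - b) * frac if scr_inj > b else b

    if intended_stage == 0:
        points += [(24.0, decay(0.5)), (48.0, decay(0.2)), (72.0, b)]
        return points, "none"

    if intended_stage == 1:
        target = b + rng.uniform(0.32, 0.38)
        feasible = target < min(1.94 * b, 0.97 * min(4.0, scr_ceiling))
        if feasible and rng.random() < 0.6:
            points += [(24.0, decay(0.5)), (48.0, b), (72.0, target)]
            return points, "creat"
        points += [(24.0, decay(0.5)), (48.0, decay(0.2)), (72.0, b)]
        return points, "urine"

    if intended_stage == 2:
        target = rng.uniform(2.2, 2.8) * b
        feasible = target < 0.97 * min(4.0, scr_ceiling)
        if feasible and rng.random() < 0.7:
            # creatinine already climbing on day 1, as in real AKI courses
            day1 = max(decay(0.5), b + 0.5 * (target - b))
            points += [(24.0, day1), (48.0, max(1.5 * b, day1)), (72.0, target)]
            return points, "creat"
        points += [(24.0, decay(0.5)), (48.0, decay(0.2)), (72.0, b)]
        return points, "urine"

    # stage 3: a >= 3x baseline ratio always qualifies, no ceiling needed
    if rng.random() < 0.7:
        target = rng.uniform(3.2, 3.8) * b
        day1 = max(decay(0.5), b + 0.5 * (2.5 * b - b))
        points += [(24.0, day1), (48.0, max(1.8 * b, day1)), (72.0, target)]
        return points, "creat"
    points += [(24.0, decay(0.5)), (48.0, decay(0.2)), (72.0, b)]
    return points, "urine"


def _build_urine(
    rng: np.random.Generator, intended_stage: int, day3_route: str
) -> np.ndarray:
    """Hourly urine rates (mL/kg/h) for 72 h; a low-output window is
    carved out when the urine axis must carry the day-3 stage."""
    rates = np.clip(rng.normal(2.0, 0.25, 72), 1.3, None)
    if day3_route != "urine":
        return rates
    if intended_stage == 1:
        rates[52:60] = rng.uniform(0.35, 0.45, 8)  # 8 h < 0.5
    elif intended_stage == 2:
        rates[46:62] = rng.uniform(0.35, 0.45, 16)  # 16 h < 0.5
    elif intended_stage == 3:
        if rng.random() < 0.5:
            rates[47:71] = rng.uniform(0.10, 0.25, 24)  # 24 h < 0.3
        else:
            rates[50:64] = 0.0  # anuria 14 h
    return rates


def _generate_patient(
    rng: np.random.Generator,
    idx: int,
    cfg: CohortConfig,
    analysis: AnalysisConfig,
) -> tuple[PatientRecord, MeasurementSeries, dict]:
    pid = f"P{idx:05d}"
    age = rng.uniform(*cfg.age_months_range)
    sex = "male" if rng.random() < cfg.sex_male_frac else "female"
    height = _height_cm(age, rng)
    weight = _weight_kg(age, rng)
    diagnosis = DIAGNOSES[rng.choice(len(DIAGNOSES), p=np.asarray(cfg.diagnosis_mix))]
    k = analysis.schwartz.k_for(age, sex)
    window = analysis.rai.window_h

    # latent labels
    ra = rng.random() < cfg.p_ra_positive
    p_aki = cfg.p_aki_given_ra_pos if ra else cfg.p_aki_given_ra_neg
    p_sev = cfg.p_severe_given_ra_pos if ra else cfg.p_severe_given_ra_neg
    aki = rng.random() < p_aki
    severe = aki and rng.random() < (p_sev / p_aki if p_aki > 0 else 0.0)
    if severe:
        p3 = cfg.p_stage3_given_severe_ra_pos if ra else cfg.p_stage3_given_severe_ra_neg
        stage = 3 if rng.random() < p3 else 2
    else:
        stage = 1 if aki else 0

    vent = rng.random() < (cfg.p_vent_given_ra_pos if ra else cfg.p_vent_given_ra_neg)
    ino = rng.random() < (
        cfg.p_inotrope_given_ra_pos if ra else cfg.p_inotrope_given_ra_neg
    )
    transplant = rng.random() < cfg.p_transplant
    risk = 5 if (vent or ino) else (3 if transplant else 1)

    # baseline creatinine: resolved exactly the way the pipeline will
    median = cfg.baseline_scr_median_infant + (
        cfg.baseline_scr_median_adolescent - cfg.baseline_scr_median_infant
    ) * age / 168.0
    b_raw = median * math.exp(rng.normal(0.0, cfg.baseline_scr_log_sd))
    has_hist = rng.random() < cfg.p_historical_baseline
    baseline_field = b_raw if has_hist else None
    resolved = resolve_baseline_scr(
        baseline_field, height, k, analysis.baseline.assumed_ecrcl
    ).baseline_scr

    scr_ceiling = k * height / 35.0  # creatinine at which eGFR drops below 35

    # injury tier compatible with the latent RA status
    if ra:
        choices = [t for t in (1, 2, 4, 8) if t >= _MIN_TIER_FOR_RA[risk]]
        weights = np.array([0.6, 0.3, 0.1][: len(choices)])
    else:
        choices = [t for t in (1, 2, 4) if t <= _MAX_TIER_FOR_NOT_RA[risk]]
        weights = np.array([0.7, 0.2, 0.1][: len(choices)])
    tier = int(rng.choice(choices, p=weights / weights.sum()))
    if cfg.label_noise > 0 and rng.random() < cfg.label_noise:
        tier = int(rng.choice([1, 2, 4, 8]))  # deliberately break correspondence
    d, f, route = _plan_injury(
        rng, tier, cfg.injury_route_mix, resolved, scr_ceiling, stage
    )

    scr_points, day3_route = _build_scr_trajectory(
        rng, resolved, d, window, stage, scr_ceiling
    )
    urine_rates = _build_urine(rng, stage, day3_route)

    entries: list[tuple[float, str, float]] = []
    entries += [(t, "scr", v) for t, v in scr_points]
    entries += [
        (float(h), "urine_output", float(urine_rates[h] * weight)) for h in range(72)
    ]
    # fluids: hourly for the first 24 h; the net balance over the
    # assessment window realises the planned %FO
    net_ml = f / 100.0 * weight * 1000.0
    n_window = int(window)
    base_in = 6.0 * weight
    for h in range(24):
        fin = base_in + (net_ml / n_window if h < n_window else 0.0)
        entries.append((float(h), "fluid_in", max(0.0, fin)))
        entries.append((float(h), "fluid_out", base_in))
    if vent:
        entries += [(1.0, "ventilation_on", 1.0), (71.5, "ventilation_off", 0.0)]
    if ino:
        entries += [(2.0, "inotrope_on", 1.0), (70.5, "inotrope_off", 0.0)]

    los = _truncnorm_min(
        rng,
        cfg.los_mean_ra_pos if ra else cfg.los_mean_ra_neg,
        cfg.los_sd_ra_pos if ra else cfg.los_sd_ra_neg,
        3.0,
    )
    dialysis = rng.random() < (
        cfg.p_dialysis_given_ra_pos if ra else cfg.p_dialysis_given_ra_neg
    )
    died = rng.random() < (cfg.p_death_given_ra_pos if ra else cfg.p_death_given_ra_neg)
    prism_shift = (
        cfg.prism_severe_shift if severe else (cfg.prism_aki_shift if aki else 0.0)
    )
    prism = max(0.0, round(rng.normal(cfg.prism_mean + prism_shift, cfg.prism_sd)))

    record = PatientRecord(
        patient_id=pid,
        age_months=age,
        sex=sex,
        height_cm=height,
        admission_weight_kg=weight,
        diagnosis=diagnosis,
        ckd_flag=False,
        consent_flag=True,
        transplant_flag=transplant,
        prism2=prism,
        picu_los_days=los,
        died=died,
        dialysis_flag=dialysis,
        baseline_scr=baseline_field,
    )
    series = MeasurementSeries.from_entries(pid, entries)
    truth = {
        "patient_id": pid,
        "ra_latent": ra,
        "intended_stage": stage,
        "risk_score": risk,
        "injury_tier": tier,
        "injury_route": route,
        "day3_route": day3_route,
        "decline_pct": d,
        "fo_pct": f,
        "resolved_baseline_scr": resolved,
    }
    return record, series, truth


def generate_cohort_with_truth(
    config: CohortConfig, analysis: AnalysisConfig | None = None
) -> tuple[list[PatientRecord], list[MeasurementSeries], pd.DataFrame]:
    """Generate a cohort plus the latent ground-truth labels.

    Deterministic given ``config.seed``; the analysis config passed here
    must match the one later used for scoring for the labels to round-trip
    exactly.
    """
    config.validate()
    analysis = analysis or AnalysisConfig()
    rng = np.random.default_rng(config.seed)
    records, series, truths = [], [], []
    for i in range(config.n_patients):
        r, s, t = _generate_patient(rng, i, config, analysis)
        records.append(r)
        series.append(s)
        truths.append(t)
    truth_df = pd.DataFrame(
        truths,
        columns=[
            "patient_id",
            "ra_latent",
            "intended_stage",
            "risk_score",
            "injury_tier",
            "injury_route",
            "day3_route",
            "decline_pct",
            "fo_pct",
            "resolved_baseline_scr",
        ],
    )
    return records, series, truth_df


def generate_cohort(
    config: CohortConfig, analysis: AnalysisConfig | None = None
) -> tuple[list[PatientRecord], list[MeasurementSeries]]:
    records, series, _ = generate_cohort_with_truth(config, analysis)
    return records, series


def generate_admission_log(
    config: CohortConfig,
    n_ckd: int = 29,
    n_short_stay: int = 30,
    n_no_consent: int = 16,
    analysis: AnalysisConfig | None = None,
) -> tuple[list[PatientRecord], list[MeasurementSeries]]:
    """An admission log: the eligible cohort plus disjoint ineligible
    encounters (pre-existing CKD, stays under 72 h, consent not
    obtained), shuffled deterministically."""
    records, series = generate_cohort(config, analysis)
    rng = np.random.default_rng(config.seed + 1)
    extra_records: list[PatientRecord] = []
    extra_series: list[MeasurementSeries] = []
    reasons = ["ckd"] * n_ckd + ["short"] * n_short_stay + ["consent"] * n_no_consent
    for j, reason in enumerate(reasons):
        pid = f"X{j:05d}"
        age = rng.uniform(2.0, 168.0)
        rec = PatientRecord(
            patient_id=pid,
            age_months=age,
            sex="male" if rng.random() < 0.5 else "female",
            height_cm=_height_cm(age, rng),
            admission_weight_kg=_weight_kg(age, rng),
            diagnosis=DIAGNOSES[int(rng.choice(len(DIAGNOSES)))],
            ckd_flag=reason == "ckd",
            consent_flag=reason != "consent",
            transplant_flag=False,
            prism2=float(max(0.0, round(rng.normal(12.0, 6.0)))),
            picu_los_days=float(rng.uniform(0.2, 2.5)) if reason == "short" else 5.0,
            died=False,
            dialysis_flag=False,
            baseline_scr=None,
        )
        extra_records.append(rec)
        extra_series.append(MeasurementSeries.from_entries(pid, []))
    all_records = records + extra_records
    all_series = series + extra_series
    order = rng.permutation(len(all_records))
    return [all_records[i] for i in order], [all_series[i] for i in order]
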