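import numpy as np
import pytest

from rai_toolkit import AnalysisConfig, day3_outcome, scr_stage, uop_stage
from rai_toolkit.kdigo import KDIGOAssessment, StagingError
from rai_toolkit.physiology import BaselineResolution

from conftest import make_record, make_series

K = 0.413
HEIGHT = 110.0
WEIGHT = 10.0


def _baseline(b):
    return BaselineResolution(b, "historical_minimum")


def _scr_series(points):
    return make_series([(t, "scr", v) for t, v in points])


def _uop_series(rates_mlkg, weight=WEIGHT):
    return make_series(
        [(float(h), "urine_output", r * weight) for h, r in enumerate(rates_mlkg)]
    )


# ---------------------------------------------------------------------------
# independent brute-force oracles


def oracle_scr_stage(points, baseline, height=HEIGHT, k=K, canonical=False):
    """Direct rule-by-rule application over every value pair."""
    pts = [(0.0, baseline)] + list(points)
    stage = 0
    for ti, vi in pts:
        for tj, vj in pts:
            if tj <= ti and ti - tj <= 48.0 and vi - vj >= 0.3:
                stage = max(stage, 1)
    for _, v in pts[1:]:
        r = v / baseline
        if canonical and 1.5 <= r < 2.0:
            stage = max(stage, 1)
        if 2.0 <= r < 3.0:
            stage = max(stage, 2)
        if r >= 3.0 or v > 4.0 or k * height / v < 35.0:
            stage = 3
    return stage


def oracle_uop_stage(rates):
    """Enumerate every contiguous hourly window."""
    stage = 0
    n = len(rates)
    for i in range(n):
        for j in range(i + 1, n + 1):
            w = rates[i:j]
            length = j - i
            mean = sum(w) / length
            if 6 <= length < 12 and mean < 0.5:
                stage = max(stage, 1)
            if length >= 13 and mean < 0.5:
                stage = max(stage, 2)
            if length >= 24 and mean < 0.3:
                stage = 3
            if length >= 13 and max(w) == 0.0:
                stage = 3
    return stage


# ---------------------------------------------------------------------------
# creatinine axis


def test_doubling_with_delta_is_stage_two():
    series = _scr_series([(24.0, 0.5), (48.0, 0.9)])
    stage, fired = scr_stage(series, _baseline(0.4), 3, HEIGHT, K)
    assert stage == 2
    assert "delta_scr_48h" in fired and "ratio_2x_7d" in fired


def test_absolute_creatinine_above_four_is_stage_three():
    series = _scr_series([(48.0, 4.5)])
    stage, fired = scr_stage(series, _baseline(2.0), 3, HEIGHT, K)
    assert stage == 3 and "scr_gt_4" in fired


def test_flat_creatinine_is_stage_zero():
    series = _scr_series([(24.0, 0.4), (48.0, 0.4), (72.0, 0.4)])
    stage, fired = scr_stage(series, _baseline(0.4), 3, HEIGHT, K)
    assert stage == 0 and fired == []


def test_low_clearance_is_stage_three():
    # 0.413 * 110 / 1.5 = 30.3 < 35
    series = _scr_series([(48.0, 1.5)])
    stage, fired = scr_stage(series, _baseline(0.9), 3, HEIGHT, K)
    assert stage == 3 and "egfr_lt_35" in fired


def test_canonical_switch_adds_15x_criterion():
    series = _scr_series([(48.0, 0.68)])  # ratio 1.7, delta 0.28
    stage_default, _ = scr_stage(series, _baseline(0.4), 3, HEIGHT, K, canonical=False)
    stage_canonical, fired = scr_stage(series, _baseline(0.4), 3, HEIGHT, K, canonical=True)
    assert stage_default == 0
    assert stage_canonical == 1 and "ratio_15x_7d" in fired


def test_no_creatinine_raises():
    with pytest.raises(StagingError):
        scr_stage(make_series([]), _baseline(0.4), 3, HEIGHT, K)


# ---------------------------------------------------------------------------
# urine axis


@pytest.mark.parametrize(
    "low_rate,low_hours,expected",
    [
        (0.2, 24, 3),  # < 0.3 mL/kg/h for 24 h
        (0.4, 8, 1),  # < 0.5 for 8 h (6-12 h band)
        (0.0, 13, 3),  # anuria for more than 12 h
        (0.4, 16, 2),  # < 0.5 for more than 12 h
    ],
)
def test_uop_stage_examples(low_rate, low_hours, expected):
    rates = [2.0] * 72
    rates[30 : 30 + low_hours] = [low_rate] * low_hours
    stage, _ = uop_stage(_uop_series(rates), WEIGHT, 3)
    assert stage == expected


def test_normal_urine_is_stage_zero():
    stage, fired = uop_stage(_uop_series([2.0] * 72), WEIGHT, 3)
    assert stage == 0 and fired == []


def test_missing_urine_data_degrades_to_stage_zero():
    stage, fired = uop_stage(make_series([(0.0, "scr", 0.5)]), WEIGHT, 3)
    assert stage == 0 and fired == []


# ---------------------------------------------------------------------------
# combined day-3 outcome


def test_combined_stage_is_max_of_axes():
    record = make_record(baseline_scr=0.4, height_cm=HEIGHT, admission_weight_kg=WEIGHT)
    rates = [2.0] * 72
    rates[40:56] = [0.4] * 16  # uop stage 2
    entries = [(float(h), "urine_output", r * WEIGHT) for h, r in enumerate(rates)]
    # delta 0.35 between 48 h and 72 h -> scr stage 1
    entries += [(0.0, "scr", 0.4), (48.0, "scr", 0.4), (72.0, "scr", 0.75)]
    assessment = day3_outcome(record, make_series(entries), _baseline(0.4))
    assert (assessment.scr_stage, assessment.uop_stage) == (1, 2)
    assert assessment.combined_stage == 2 and assessment.severe


def test_dialysis_does_not_force_stage_three():
    record = make_record(
        dialysis_flag=True, baseline_scr=0.4, height_cm=HEIGHT, admission_weight_kg=WEIGHT
    )
    entries = [(float(h), "urine_output", 2.0 * WEIGHT) for h in range(72)]
    entries += [(0.0, "scr", 0.4), (48.0, "scr", 0.4), (72.0, "scr", 0.4)]
    assessment = day3_outcome(record, make_series(entries), _baseline(0.4))
    assert assessment.combined_stage == 0 and not assessment.severe
    assert record.dialysis_flag  # recorded as an outcome, not a stage


def test_assessment_invariants_enforced():
    with pytest.raises(ValueError):
        KDIGOAssessment("p", 3, scr_stage=1, uop_stage=2, combined_stage=1,
                        severe=False, criteria_fired=["delta_scr_48h"])
    with pytest.raises(ValueError):
        KDIGOAssessment("p", 3, scr_stage=0, uop_stage=0, combined_stage=0,
                        severe=False, criteria_fired=["delta_scr_48h"])


# ---------------------------------------------------------------------------
# properties


def _random_case(rng):
    b = rng.uniform(0.3, 1.2)
    n_scr = rng.integers(1, 6)
    times = np.sort(rng.uniform(0, 96, n_scr))
    values = b * np.exp(np.cumsum(rng.normal(0.1, 0.45, n_scr)))
    values = np.clip(values, 0.05, 8.0)
    rates = np.round(rng.lognormal(0.2, 0.7, int(rng.integers(10, 97))), 2)
    for _ in range(rng.integers(0, 3)):
        start = int(rng.integers(0, len(rates)))
        length = int(rng.integers(4, 30))
        rates[start : start + length] = rng.choice([0.0, 0.1, 0.25, 0.4])
    return b, list(zip(times.tolist(), values.tolist())), rates.tolist()


def test_staging_matches_bruteforce_oracle_on_random_series():
    rng = np.random.default_rng(42)
    for _ in range(60):
        b, scr_points, rates = _random_case(rng)
        series = _scr_series(scr_points)
        got, _ = scr_stage(series, _baseline(b), 4, HEIGHT, K)
        assert got == oracle_scr_stage(scr_points, b)
        got_u, _ = uop_stage(_uop_series(rates), WEIGHT, 4)
        assert got_u == oracle_uop_stage(rates)


def test_null_cohort_has_no_aki(small_cohort):
    """Baseline creatinine held and normal urine output stage nobody."""
    records, _, _ = small_cohort
    for record in records[:20]:
        b = record.baseline_scr or 0.5
        entries = [(t, "scr", b) for t in (0.0, 24.0, 48.0, 72.0)]
        entries += [
            (float(h), "urine_output", 2.0 * record.admission_weight_kg)
            for h in range(72)
        ]
        assessment = day3_outcome(record, make_series(entries), _baseline(b))
        assert assessment.combined_stage == 0


def test_staging_monotone_under_perturbation():
    rng = np.random.default_rng(3)
    for _ in range(40):
        b, scr_points, rates = _random_case(rng)
        series = _scr_series(scr_points)
        stage0, _ = scr_stage(series, _baseline(b), 4, HEIGHT, K)
        idx = int(rng.integers(0, len(scr_points)))
        bumped = [
            (t, v + (0.4 if i == idx else 0.0)) for i, (t, v) in enumerate(scr_points)
        ]
        stage1, _ = scr_stage(_scr_series(bumped), _baseline(b), 4, HEIGHT, K)
        assert stage1 >= stage0

        u0, _ = uop_stage(_uop_series(rates), WEIGHT, 4)
        reduced = [r * 0.5 for r in rates]
        u1, _ = uop_stage(_uop_series(reduced), WEIGHT, 4)
        assert u1 >= u0
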