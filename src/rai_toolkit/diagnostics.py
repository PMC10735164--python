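"""Diagnostic evaluation: contingency tables, test metrics, ROC curves,
and the group-comparison report.

The report mirrors the structure of a clinical validation study: a
comparison of AKI vs no-AKI groups, a comparison of renal-angina positive
vs negative groups (per-stage AKI counts, support use, dialysis, length
of stay, mortality), and a head-to-head table of predictor performance
(sensitivity/specificity/PPV/NPV and ROC-AUC) for the renal angina index
against day-0 creatinine elevation, fluid overload > 5% alone, and
illness severity (PRISM II).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
import json
import math
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .cohort import MeasurementSeries, PatientRecord
from .config import AnalysisConfig
from .kdigo import KDIGOAssessment
from .physiology import BaselineResolution, schwartz_ecrcl
from .scoring import RAIResult


class DiagnosticsError(Exception):
    pass


@dataclass
class TwoByTwo:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fn], [self.fp, self.tn]], dtype=float)


@dataclass
class MetricSet:
    """Proportion metrics; an undefined metric (zero denominator) is NaN,
    never silently 0."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    auc: float = math.nan


@dataclass
class GroupRow:
    variable: str
    value_a: str
    value_b: str
    test: str
    p_value: float | None  # None = not computable


@dataclass
class DiagnosticReport:
    group_label_a: str
    group_label_b: str
    group_rows: list[GroupRow] = field(default_factory=list)
    tables: dict[str, TwoByTwo] = field(default_factory=dict)
    metrics: dict[str, MetricSet] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "groups": [self.group_label_a, self.group_label_b],
            "group_rows": [
                {
                    "variable": r.variable,
                    "value_a": r.value_a,
                    "value_b": r.value_b,
                    "test": r.test,
                    "p_value": r.p_value,
                    "p_text": format_p(r.p_value),
                }
                for r in self.group_rows
            ],
            "tables": {
                name: {"tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn}
                for name, t in self.tables.items()
            },
            "metrics": {
                name: {
                    k: (None if math.isnan(v) else v)
                    for k, v in (
                        ("sensitivity", m.sensitivity),
                        ("specificity", m.specificity),
                        ("ppv", m.ppv),
                        ("npv", m.npv),
                        ("auc", m.auc),
                    )
                }
                for name, m in self.metrics.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_markdown(self) -> str:
        lines = [
            f"## Group comparison: {self.group_label_a} vs {self.group_label_b}",
            "",
            f"| Variable | {self.group_label_a} | {self.group_label_b} | Test | P |",
            "|---|---|---|---|---|",
        ]
        for r in self.group_rows:
            lines.append(
                f"| {r.variable} | {r.value_a} | {r.value_b} | {r.test} "
                f"| {format_p(r.p_value)} |"
            )
        lines += [
            "",
            "## Predictor performance",
            "",
            "| Predictor | Sensitivity | Specificity | PPV | NPV | AUC |",
            "|---|---|---|---|---|---|",
        ]
        for name, m in self.metrics.items():
            cells = [
                "NA" if math.isnan(v) else format_pct(100 * v) + "%"
                for v in (m.sensitivity, m.specificity, m.ppv, m.npv)
            ]
            auc = "NA" if math.isnan(m.auc) else f"{m.auc:.3f}"
            lines.append(f"| {name} | {' | '.join(cells)} | {auc} |")
        return "\n".join(lines) + "\n"


def format_pct(x: float) -> str:
    """One decimal, round half up (clinical-table style)."""
    return str(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def format_p(p: float | None) -> str:
    if p is None:
        return "NA"
    if p < 0.001:
        return "<.001"
    return f"{p:.4f}"


def contingency(
    predictor_positive: Sequence[bool], outcome_positive: Sequence[bool]
) -> TwoByTwo:
    pred = np.asarray(predictor_positive, dtype=bool)
    out = np.asarray(outcome_positive, dtype=bool)
    if pred.shape != out.shape:
        raise DiagnosticsError("predictor and outcome vectors differ in length")
    return TwoByTwo(
        tp=int(np.sum(pred & out)),
        fp=int(np.sum(pred & ~out)),
        fn=int(np.sum(~pred & out)),
        tn=int(np.sum(~pred & ~out)),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def metrics_from_2x2(t: TwoByTwo) -> MetricSet:
    return MetricSet(
        sensitivity=_ratio(t.tp, t.tp + t.fn),
        specificity=_ratio(t.tn, t.tn + t.fp),
        ppv=_ratio(t.tp, t.tp + t.fp),
        npv=_ratio(t.tn, t.tn + t.fn),
    )


def roc_auc(
    score: Sequence[float], outcome_positive: Sequence[bool]
) -> tuple[np.ndarray, float]:
    """ROC curve points (FPR, TPR) and trapezoidal AUC with half credit
    for ties (the Mann-Whitney U / midrank equivalence)."""
    s = np.asarray(score, dtype=float)
    y = np.asarray(outcome_positive, dtype=bool)
    if s.shape != y.shape:
        raise DiagnosticsError("score and outcome vectors differ in length")
    if y.all() or not y.any():
        raise DiagnosticsError("ROC requires both outcome classes")
    fpr, tpr, _ = _sk_roc_curve(y.astype(int), s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def chi_square(
    table: TwoByTwo | Sequence[Sequence[float]], yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on an r x c table of counts."""
    arr = table.as_array() if isinstance(table, TwoByTwo) else np.asarray(table, float)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise DiagnosticsError("chi_square needs at least a 2x2 table")
    if np.any(arr < 0):
        raise DiagnosticsError("counts must be >= 0")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise DiagnosticsError("chi_square undefined with a zero marginal")
    res = stats.chi2_contingency(arr, correction=yates)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (midranks, tie-corrected normal
    approximation); returns U for the first sample."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise DiagnosticsError("both samples must be nonempty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _n_pct(flags_a: np.ndarray, flags_b: np.ndarray) -> tuple[str, str]:
    fa = f"{int(flags_a.sum())} ({format_pct(100 * flags_a.mean())}%)" if flags_a.size else "0"
    fb = f"{int(flags_b.sum())} ({format_pct(100 * flags_b.mean())}%)" if flags_b.size else "0"
    return fa, fb


def _mean_sd(x_a: np.ndarray, x_b: np.ndarray) -> tuple[str, str]:
    fmt = lambda x: f"{x.mean():.1f} ± {x.std(ddof=1):.1f}" if x.size > 1 else "NA"
    return fmt(x_a), fmt(x_b)


def _binary_row(
    name: str, flags: np.ndarray, split: np.ndarray, yates: bool
) -> GroupRow:
    fa, fb = flags[split], flags[~split]
    va, vb = _n_pct(fa, fb)
    try:
        _, p = chi_square(contingency(split, flags), yates=yates)
    except DiagnosticsError:
        p = None
    return GroupRow(name, va, vb, "chi-square", p)


def _continuous_row(name: str, x: np.ndarray, split: np.ndarray) -> GroupRow:
    xa, xb = x[split], x[~split]
    va, vb = _mean_sd(xa, xb)
    try:
        _, p = mann_whitney(xa, xb)
    except DiagnosticsError:
        p = None
    return GroupRow(name, va, vb, "Mann-Whitney U", p)


def day0_scr_elevated(
    record: PatientRecord,
    series: MeasurementSeries,
    baseline: BaselineResolution,
    config: AnalysisConfig,
) -> tuple[bool, float]:
    """Day-0 comparator: does the admission-day creatinine meet any
    stage-1+ creatinine criterion versus baseline?  Also returns the
    day-0/baseline ratio as the continuous score for ROC analysis."""
    t, v = series.select("scr")
    mask = t <= 24.0
    if not mask.any():
        return False, 1.0
    scr0 = float(v[np.flatnonzero(mask)[-1]])
    b = baseline.baseline_scr
    k = config.schwartz.k_for(record.age_months, record.sex)
    elevated = (
        scr0 - b >= 0.3
        or scr0 / b >= 2.0
        or scr0 > 4.0
        or schwartz_ecrcl(record.height_cm, scr0, k) < 35.0
    )
    return bool(elevated), scr0 / b


def build_report(
    records: Sequence[PatientRecord],
    rai_results: Sequence[RAIResult],
    assessments: Sequence[KDIGOAssessment],
    baselines: Sequence[BaselineResolution],
    series: Sequence[MeasurementSeries],
    config: AnalysisConfig | None = None,
) -> dict[str, DiagnosticReport]:
    """Build the three evaluation reports from aligned per-patient inputs.

    Returns ``{"aki_vs_no_aki": ..., "ra_pos_vs_ra_neg": ...,
    "predictor_performance": ...}``; the last carries the 2x2 tables and
    metric sets for the four predictors against severe day-3 AKI.
    """
    config = config or AnalysisConfig()
    n = len(records)
    if not (len(rai_results) == len(assessments) == len(baselines) == len(series) == n):
        raise DiagnosticsError("per-patient inputs must be aligned")
    yates = config.diagnostics.yates_correction

    rai = np.array([r.rai for r in rai_results], float)
    ra_pos = np.array([r.ra_positive for r in rai_results], bool)
    fo = np.array([r.fo_pct for r in rai_results], float)
    stage = np.array([a.combined_stage for a in assessments], int)
    aki = stage >= 1
    severe = stage >= 2
    male = np.array([r.sex == "male" for r in records], bool)
    age = np.array([r.age_months for r in records], float)
    los = np.array([r.picu_los_days for r in records], float)
    died = np.array([r.died for r in records], bool)
    dialysis = np.array([r.dialysis_flag for r in records], bool)
    prism = np.array([r.prism2 for r in records], float)
    vent = np.array(
        [s.support_active("ventilation", np.inf) for s in series], bool
    )
    ino = np.array([s.support_active("inotrope", np.inf) for s in series], bool)
    day0 = [
        day0_scr_elevated(r, s, b, config)
        for r, s, b in zip(records, series, baselines)
    ]
    day0_flag = np.array([d[0] for d in day0], bool)
    day0_ratio = np.array([d[1] for d in day0], float)

    # --- AKI vs no-AKI -------------------------------------------------
    aki_rep = DiagnosticReport("AKI", "no AKI")
    aki_rep.group_rows.append(_binary_row("Male", male, aki, yates))
    aki_rep.group_rows.append(_continuous_row("Age (months)", age, aki))
    for dx in sorted({r.diagnosis for r in records}):
        flags = np.array([r.diagnosis == dx for r in records], bool)
        aki_rep.group_rows.append(_binary_row(f"Diagnosis: {dx}", flags, aki, yates))
    aki_rep.group_rows.append(_binary_row("RAI positive", ra_pos, aki, yates))
    aki_rep.group_rows.append(_continuous_row("RAI score", rai, aki))
    aki_rep.group_rows.append(_binary_row("Inotropes use", ino, aki, yates))
    aki_rep.group_rows.append(_binary_row("Mechanical ventilation", vent, aki, yates))
    aki_rep.group_rows.append(_binary_row("Dialysis", dialysis, aki, yates))
    aki_rep.group_rows.append(_continuous_row("PICU LOS (days)", los, aki))
    aki_rep.group_rows.append(_binary_row("Mortality", died, aki, yates))

    # --- RA+ vs RA- ----------------------------------------------------
    ra_rep = DiagnosticReport("RA+", "RA-")
    for st in (1, 2, 3):
        ra_rep.group_rows.append(
            _binary_row(f"Day 3 AKI stage {st}", stage == st, ra_pos, yates)
        )
    ra_rep.group_rows.append(
        _binary_row("Severe day 3 AKI (stages 2&3)", severe, ra_pos, yates)
    )
    ra_rep.group_rows.append(_binary_row("Day 3 AKI (all stages)", aki, ra_pos, yates))
    ra_rep.group_rows.append(_binary_row("Inotropes use", ino, ra_pos, yates))
    ra_rep.group_rows.append(_binary_row("Mechanical ventilation", vent, ra_pos, yates))
    ra_rep.group_rows.append(_binary_row("Dialysis", dialysis, ra_pos, yates))
    ra_rep.group_rows.append(_continuous_row("PICU LOS (days)", los, ra_pos))
    ra_rep.group_rows.append(_binary_row("Mortality", died, ra_pos, yates))
    ra_rep.tables["ra_vs_severe_aki"] = contingency(ra_pos, severe)
    ra_rep.tables["ra_vs_any_aki"] = contingency(ra_pos, aki)

    # --- predictor performance against severe day-3 AKI ----------------
    perf = DiagnosticReport("severe AKI", "no severe AKI")
    predictors = {
        "RAI": (ra_pos, rai),
        "Day 0 elevated serum creatinine": (day0_flag, day0_ratio),
        f"Fluid overload > {config.diagnostics.fo_threshold_pct:g}% alone": (
            fo > config.diagnostics.fo_threshold_pct,
            fo,
        ),
        "Illness severity (PRISM II)": (
            prism >= config.diagnostics.prism_threshold,
            prism,
        ),
    }
    for name, (flag, score) in predictors.items():
        table = contingency(flag, severe)
        perf.tables[name] = table
        m = metrics_from_2x2(table)
        try:
            _, m.auc = roc_auc(score, severe)
        except DiagnosticsError:
            m.auc = math.nan
        perf.metrics[name] = m

    return {
        "aki_vs_no_aki": aki_rep,
        "ra_pos_vs_ra_neg": ra_rep,
        "predictor_performance": perf,
    }


def plot_roc(
    scores: dict[str, Sequence[float]],
    outcome_positive: Sequence[bool],
    ax=None,
):
    """Plot ROC curves for named scores; returns the matplotlib axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for name, score in scores.items():
        points, auc = roc_auc(score, outcome_positive)
        ax.plot(points[:, 0], points[:, 1], label=f"{name} (AUC {auc:.3f})")
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    return ax
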