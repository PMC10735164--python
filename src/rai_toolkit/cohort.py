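"""Cohort data model, two-file delimited-text I/O and eligibility filters.

The cohort lives in two CSV files:

* a *static* file, one row per patient, with demographics, support and
  outcome fields (columns exactly the :class:`PatientRecord` fields);
* a *measurements* file in long format with columns
  ``patient_id, time_hours, kind, value`` holding the timestamped serum
  creatinine (mg/dL), hourly urine output and fluid in/out volumes (mL)
  and support on/off events.

Creatinine may be recorded in µmol/L; a per-file unit declaration (or an
optional per-row ``units`` column) converts to the canonical internal unit
mg/dL with the factor 88.4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UMOL_PER_MGDL = 88.4

DIAGNOSES = (
    "respiratory",
    "cardiovascular",
    "neurological",
    "sepsis",
    "shock",
    "gastrointestinal",
    "surgical_trauma",
    "endocrinal",
    "other",
)

MEASUREMENT_KINDS = (
    "scr",
    "urine_output",
    "fluid_in",
    "fluid_out",
    "ventilation_on",
    "ventilation_off",
    "inotrope_on",
    "inotrope_off",
)

STATIC_COLUMNS = (
    "patient_id",
    "age_months",
    "sex",
    "height_cm",
    "admission_weight_kg",
    "diagnosis",
    "ckd_flag",
    "consent_flag",
    "transplant_flag",
    "prism2",
    "picu_los_days",
    "died",
    "dialysis_flag",
    "baseline_scr",
)

MEASUREMENT_COLUMNS = ("patient_id", "time_hours", "kind", "value")

# Eligibility window: ages 1 month to 14 years inclusive, minimum 72 h stay.
AGE_MIN_MONTHS = 1.0
AGE_MAX_MONTHS = 168.0
MIN_STAY_DAYS = 3.0


class CohortError(Exception):
    """Base class for cohort I/O and validation errors."""


class SchemaError(CohortError):
    """A required column is missing or malformed."""


class ReferentialError(CohortError):
    """Measurements reference a patient_id absent from the static file."""


class ParseError(CohortError):
    """A value could not be parsed; carries the offending line number."""


@dataclass
class PatientRecord:
    patient_id: str
    age_months: float
    sex: str
    height_cm: float
    admission_weight_kg: float
    diagnosis: str
    ckd_flag: bool
    consent_flag: bool
    transplant_flag: bool
    prism2: float
    picu_los_days: float
    died: bool
    dialysis_flag: bool
    baseline_scr: float | None = None

    def __post_init__(self) -> None:
        if self.age_months <= 0:
            raise ValueError(f"{self.patient_id}: age_months must be > 0")
        if self.admission_weight_kg <= 0:
            raise ValueError(f"{self.patient_id}: admission_weight_kg must be > 0")
        if self.height_cm <= 0:
            raise ValueError(f"{self.patient_id}: height_cm must be > 0")
        if self.picu_los_days < 0:
            raise ValueError(f"{self.patient_id}: picu_los_days must be >= 0")
        if self.sex not in ("male", "female"):
            raise ValueError(f"{self.patient_id}: unknown sex {self.sex!r}")
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"{self.patient_id}: unknown diagnosis {self.diagnosis!r}")


@dataclass
class MeasurementSeries:
    """Timestamped measurements for one patient, sorted by time.

    Stored as parallel arrays for speed; ``entries`` exposes the
    (time, kind, value) tuples.
    """

    patient_id: str
    times: np.ndarray
    kinds: np.ndarray
    values: np.ndarray

    @classmethod
    def from_entries(
        cls, patient_id: str, entries: Iterable[tuple[float, str, float]]
    ) -> "MeasurementSeries":
        rows = list(entries)
        times = np.asarray([r[0] for r in rows], dtype=float)
        kinds = np.asarray([r[1] for r in rows], dtype=object)
        values = np.asarray([r[2] for r in rows], dtype=float)
        order = np.argsort(times, kind="stable")
        series = cls(patient_id, times[order], kinds[order], values[order])
        series.validate()
        return series

    @property
    def entries(self) -> list[tuple[float, str, float]]:
        return list(zip(self.times.tolist(), self.kinds.tolist(), self.values.tolist()))

    def select(self, kind: str) -> tuple[np.ndarray, np.ndarray]:
        mask = self.kinds == kind
        return self.times[mask], self.values[mask]

    def validate(self) -> None:
        if np.any(self.times < 0):
            raise ValueError(f"{self.patient_id}: measurement times must be >= 0")
        if np.any(np.diff(self.times) < 0):
            raise ValueError(f"{self.patient_id}: entries must be sorted by time")
        for kind in self.kinds:
            if kind not in MEASUREMENT_KINDS:
                raise ValueError(f"{self.patient_id}: unknown measurement kind {kind!r}")
        _, scr = self.select("scr")
        if np.any(scr <= 0):
            raise ValueError(f"{self.patient_id}: creatinine values must be > 0")
        for kind in ("urine_output", "fluid_in", "fluid_out"):
            _, vol = self.select(kind)
            if np.any(vol < 0):
                raise ValueError(f"{self.patient_id}: {kind} volumes must be >= 0")
        for channel in ("ventilation", "inotrope"):
            on_t, _ = self.select(f"{channel}_on")
            off_t, _ = self.select(f"{channel}_off")
            events = sorted(
                [(t, 1) for t in on_t] + [(t, 0) for t in off_t], key=lambda e: e[0]
            )
            state = 0
            for _, ev in events:
                if ev == state:
                    raise ValueError(
                        f"{self.patient_id}: {channel} on/off events must alternate"
                    )
                state = ev

    def support_active(
        self, channel: str, window_end_h: float, mode: str = "any_time_in_window"
    ) -> bool:
        """Whether ventilation/inotrope support applies within the window.

        ``any_time_in_window`` is true if the channel was on at any point in
        [0, window_end_h]; ``at_assessment`` requires it on at window end.
        """
        on_t, _ = self.select(f"{channel}_on")
        off_t, _ = self.select(f"{channel}_off")
        if mode == "any_time_in_window":
            return bool(np.any(on_t <= window_end_h))
        if mode == "at_assessment":
            return int(np.sum(on_t <= window_end_h)) > int(np.sum(off_t <= window_end_h))
        raise ValueError(f"unknown support mode {mode!r}")


@dataclass
class CohortFilterReport:
    """Disjoint exclusion tally; a record failing several criteria is
    counted once with priority age > CKD > short stay > consent."""

    n_identified: int
    n_excluded_age: int
    n_excluded_ckd: int
    n_excluded_short_stay: int
    n_excluded_no_consent: int
    n_eligible: int

    def __post_init__(self) -> None:
        counts = (
            self.n_excluded_age,
            self.n_excluded_ckd,
            self.n_excluded_short_stay,
            self.n_excluded_no_consent,
            self.n_eligible,
            self.n_identified,
        )
        if any(c < 0 for c in counts):
            raise ValueError("filter report counts must be >= 0")
        if self.n_eligible != self.n_identified - (
            self.n_excluded_age
            + self.n_excluded_ckd
            + self.n_excluded_short_stay
            + self.n_excluded_no_consent
        ):
            raise ValueError("filter report counts do not sum")


def _parse_bool(raw: str, line_no: int, column: str) -> bool:
    s = str(raw).strip().lower()
    if s in ("true", "t", "1", "yes"):
        return True
    if s in ("false", "f", "0", "no"):
        return False
    raise ParseError(f"line {line_no}: cannot parse boolean {column}={raw!r}")


def _parse_float(raw: str, line_no: int, column: str) -> float:
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise ParseError(
            f"line {line_no}: cannot parse numeric {column}={raw!r}"
        ) from None


def load_cohort(
    static_path: str | Path,
    measurements_path: str | Path,
    scr_units: str = "mg/dL",
) -> tuple[list[PatientRecord], list[MeasurementSeries]]:
    """Read the two-file cohort, returning one series per patient.

    ``scr_units`` declares the creatinine unit of the measurements file
    ("mg/dL" or "umol/L"); an optional per-row ``units`` column overrides
    it.  µmol/L values are divided by 88.4.
    """
    static = pd.read_csv(static_path, dtype=str, keep_default_na=False)
    missing = [c for c in STATIC_COLUMNS if c not in static.columns]
    if missing:
        raise SchemaError(f"static file missing column(s): {', '.join(missing)}")

    records: list[PatientRecord] = []
    for idx, row in static.iterrows():
        line_no = int(idx) + 2  # header is line 1
        baseline_raw = row["baseline_scr"].strip()
        records.append(
            PatientRecord(
                patient_id=row["patient_id"],
                age_months=_parse_float(row["age_months"], line_no, "age_months"),
                sex=row["sex"],
                height_cm=_parse_float(row["height_cm"], line_no, "height_cm"),
                admission_weight_kg=_parse_float(
                    row["admission_weight_kg"], line_no, "admission_weight_kg"
                ),
                diagnosis=row["diagnosis"],
                ckd_flag=_parse_bool(row["ckd_flag"], line_no, "ckd_flag"),
                consent_flag=_parse_bool(row["consent_flag"], line_no, "consent_flag"),
                transplant_flag=_parse_bool(
                    row["transplant_flag"], line_no, "transplant_flag"
                ),
                prism2=_parse_float(row["prism2"], line_no, "prism2"),
                picu_los_days=_parse_float(
                    row["picu_los_days"], line_no, "picu_los_days"
                ),
                died=_parse_bool(row["died"], line_no, "died"),
                dialysis_flag=_parse_bool(row["dialysis_flag"], line_no, "dialysis_flag"),
                baseline_scr=(
                    _parse_float(baseline_raw, line_no, "baseline_scr")
                    if baseline_raw
                    else None
                ),
            )
        )

    meas = pd.read_csv(measurements_path, dtype=str, keep_default_na=False)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in meas.columns]
    if missing:
        raise SchemaError(f"measurements file missing column(s): {', '.join(missing)}")
    has_units_col = "units" in meas.columns

    known_ids = {r.patient_id for r in records}
    per_patient: dict[str, list[tuple[float, str, float]]] = {
        pid: [] for pid in known_ids
    }
    for idx, row in meas.iterrows():
        line_no = int(idx) + 2
        pid = row["patient_id"]
        if pid not in known_ids:
            raise ReferentialError(
                f"line {line_no}: measurements reference unknown patient_id {pid!r}"
            )
        kind = row["kind"]
        if kind not in MEASUREMENT_KINDS:
            raise SchemaError(f"line {line_no}: unknown measurement kind {kind!r}")
        t = _parse_float(row["time_hours"], line_no, "time_hours")
        v = _parse_float(row["value"], line_no, "value")
        if kind == "scr":
            units = (row["units"].strip() if has_units_col else "") or scr_units
            if units in ("umol/L", "µmol/L"):
                v /= UMOL_PER_MGDL
            elif units != "mg/dL":
                raise SchemaError(f"line {line_no}: unknown creatinine unit {units!r}")
        per_patient[pid].append((t, kind, v))

    series = [
        MeasurementSeries.from_entries(r.patient_id, per_patient[r.patient_id])
        for r in records
    ]
    return records, series


def write_cohort(
    records: Sequence[PatientRecord],
    series: Sequence[MeasurementSeries],
    static_path: str | Path,
    measurements_path: str | Path,
) -> None:
    """Write the two-file schema; round-trips through :func:`load_cohort`."""
    static = pd.DataFrame(
        [
            {
                **{c: getattr(r, c) for c in STATIC_COLUMNS if c != "baseline_scr"},
                "baseline_scr": "" if r.baseline_scr is None else repr(r.baseline_scr),
            }
            for r in records
        ],
        columns=list(STATIC_COLUMNS),
    )
    for col in ("age_months", "height_cm", "admission_weight_kg", "prism2", "picu_los_days"):
        static[col] = static[col].map(repr)
    static.to_csv(static_path, index=False)

    rows = []
    for s in series:
        for t, kind, v in zip(s.times, s.kinds, s.values):
            rows.append((s.patient_id, repr(float(t)), kind, repr(float(v))))
    pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS)).to_csv(
        measurements_path, index=False
    )


def is_eligible(record: PatientRecord) -> bool:
    return (
        AGE_MIN_MONTHS <= record.age_months <= AGE_MAX_MONTHS
        and not record.ckd_flag
        and record.picu_los_days >= MIN_STAY_DAYS
        and record.consent_flag
    )


def apply_eligibility_filters(
    records: Sequence[PatientRecord],
) -> tuple[list[PatientRecord], CohortFilterReport]:
    """Apply the study eligibility criteria.

    Retained patients are aged 1-168 months, free of chronic kidney
    disease, consented, and stayed at least 72 h.  Each excluded record is
    counted under exactly one reason (priority age > CKD > short stay >
    consent).
    """
    retained: list[PatientRecord] = []
    n_age = n_ckd = n_stay = n_consent = 0
    for r in records:
        if not (AGE_MIN_MONTHS <= r.age_months <= AGE_MAX_MONTHS):
            n_age += 1
        elif r.ckd_flag:
            n_ckd += 1
        elif r.picu_los_days < MIN_STAY_DAYS:
            n_stay += 1
        elif not r.consent_flag:
            n_consent += 1
        else:
            retained.append(r)
    report = CohortFilterReport(
        n_identified=len(records),
        n_excluded_age=n_age,
        n_excluded_ckd=n_ckd,
        n_excluded_short_stay=n_stay,
        n_excluded_no_consent=n_consent,
        n_eligible=len(retained),
    )
    logger.info(
        "eligibility: %d identified, %d eligible (age %d, CKD %d, short stay %d, "
        "no consent %d excluded)",
        report.n_identified,
        report.n_eligible,
        n_age,
        n_ckd,
        n_stay,
        n_consent,
    )
    return retained, report
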