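"""Analysis configuration.

Every judgement call in the pipeline that is not fixed by the scoring
rules themselves (Schwartz constant, assessment window, KDIGO variant,
comparator thresholds) is a config key, so sensitivity analyses are a
one-line change in a YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml


@dataclass
class SchwartzConfig:
    """Schwartz estimated-creatinine-clearance settings.

    k_mode
        ``"fixed"`` uses ``k_fixed`` for every patient (bedside Schwartz,
        default 0.413).  ``"age_sex"`` uses the original age/sex constants:
        0.45 below 12 months, 0.70 for boys of 13 years and over, 0.55
        otherwise.
    """

    k_mode: str = "fixed"
    k_fixed: float = 0.413

    def k_for(self, age_months: float, sex: str) -> float:
        if self.k_mode == "fixed":
            return self.k_fixed
        if self.k_mode == "age_sex":
            if age_months < 12:
                return 0.45
            if age_months >= 156 and sex == "male":
                return 0.70
            return 0.55
        raise ValueError(f"unknown schwartz k_mode: {self.k_mode!r}")


@dataclass
class BaselineConfig:
    """Baseline creatinine resolution: assumed normal clearance used to
    back-calculate a baseline when no pre-admission creatinine exists."""

    assumed_ecrcl: float = 120.0  # mL/min/1.73 m^2


@dataclass
class RAIConfig:
    """Renal angina assessment settings.

    window_h
        End of the assessment window in hours from admission (8-12).
    support_mode
        ``"any_time_in_window"`` counts ventilation/inotrope support active
        at any point in [0, window_h]; ``"at_assessment"`` requires support
        active at the window end.
    """

    window_h: float = 12.0
    support_mode: str = "any_time_in_window"

    def __post_init__(self) -> None:
        if not 8.0 <= self.window_h <= 12.0:
            raise ValueError("rai.window_h must lie in [8, 12] hours")
        if self.support_mode not in ("any_time_in_window", "at_assessment"):
            raise ValueError(f"unknown support_mode: {self.support_mode!r}")


@dataclass
class KDIGOConfig:
    """AKI staging settings.

    canonical
        The staging rules implemented by default omit the canonical
        1.5-1.9x creatinine-ratio stage-1 criterion; setting this flag adds
        it back for users who want consensus KDIGO.
    eval_day
        Day on which the primary outcome is staged.
    """

    canonical: bool = False
    eval_day: int = 3


@dataclass
class DiagnosticsConfig:
    """Comparator and test settings for the evaluation report."""

    prism_threshold: float = 17.0  # PRISM II dichotomisation for sens/spec
    fo_threshold_pct: float = 5.0  # "fluid overload > 5% alone" comparator
    yates_correction: bool = False


@dataclass
class AnalysisConfig:
    schwartz: SchwartzConfig = field(default_factory=SchwartzConfig)
    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    rai: RAIConfig = field(default_factory=RAIConfig)
    kdigo: KDIGOConfig = field(default_factory=KDIGOConfig)
    diagnostics: DiagnosticsConfig = field(default_factory=DiagnosticsConfig)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AnalysisConfig":
        return cls(
            schwartz=SchwartzConfig(**d.get("schwartz", {})),
            baseline=BaselineConfig(**d.get("baseline", {})),
            rai=RAIConfig(**d.get("rai", {})),
            kdigo=KDIGOConfig(**d.get("kdigo", {})),
            diagnostics=DiagnosticsConfig(**d.get("diagnostics", {})),
        )

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data.get("analysis", data))
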