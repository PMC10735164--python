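import hypothesis
import pytest

from rai_toolkit import AnalysisConfig, MeasurementSeries, PatientRecord
from rai_toolkit.simulate import default_config, generate_cohort_with_truth

hypothesis.settings.register_profile(
    "det", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("det")


def make_record(**overrides) -> PatientRecord:
    base = dict(
        patient_id="T001",
        age_months=60.0,
        sex="male",
        height_cm=110.0,
        admission_weight_kg=18.0,
        diagnosis="sepsis",
        ckd_flag=False,
        consent_flag=True,
        transplant_flag=False,
        prism2=12.0,
        picu_los_days=6.0,
        died=False,
        dialysis_flag=False,
        baseline_scr=0.5,
    )
    base.update(overrides)
    return PatientRecord(**base)


def make_series(entries, patient_id="T001") -> MeasurementSeries:
    return MeasurementSeries.from_entries(patient_id, entries)


@pytest.fixture
def analysis_config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient synthetic cohort with ground truth (seed 7)."""
    cfg = default_config()
    cfg.n_patients = 60
    cfg.seed = 7
    return generate_cohort_with_truth(cfg)
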