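import numpy as np
import pytest

from exposurekit import PatientRecord, Cohort, default_config, generate_cohort


def make_record(pid="P1", **overrides) -> PatientRecord:
    base = dict(
        patient_id=pid,
        sex="male",
        residence="urban",
        smoker="yes",
        comorbidity="copd",
        occupational_exposure="yes",
        diagnostic_group="G1a",
        tnm_stage="IV",
        p63="positive",
        pdl1="positive",
        egfr="none",
        age_years=63,
        ki67_percent=40.0,
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def small_cohort() -> Cohort:
    """Five hand-written records covering all score classes."""
    return Cohort(
        [
            make_record("A", tnm_stage="IV", comorbidity="copd",
                        p63="positive", pdl1="positive", egfr="none",
                        diagnostic_group="G1a"),              # 4 points, high
            make_record("B", tnm_stage="II", comorbidity="none",
                        p63="negative", pdl1="negative", egfr="none",
                        diagnostic_group="G1b"),              # 0 points, low
            make_record("C", tnm_stage="IV", comorbidity="diabetes",
                        p63="negative", pdl1="negative", egfr="none",
                        diagnostic_group="G2"),               # 3 points, medium
            make_record("D", sex="female", residence="rural", smoker="no",
                        tnm_stage="III", comorbidity="asthma",
                        p63="positive", pdl1="negative", egfr="exon19",
                        diagnostic_group="G3", age_years=48),  # 5 points, high
            make_record("E", tnm_stage="II", comorbidity="heart_disease",
                        p63="negative", pdl1="positive", egfr="none",
                        diagnostic_group="G1a", age_years=70,
                        ki67_percent=None),                    # 2 points, medium
        ]
    )


@pytest.fixture(scope="session")
def synthetic_cohort() -> Cohort:
    """The default study-sized synthetic cohort at a fixed seed."""
    return generate_cohort(default_config(n=131, seed=1))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
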