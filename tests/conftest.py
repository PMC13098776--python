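import numpy as np
import pandas as pd
import pytest

from cdewatch.synth import SyntheticConfig, generate_cohort


def ts(hours, base="2022-01-01"):
    """Timestamp a given number of hours after a fixed base date."""
    return pd.Timestamp(base) + pd.Timedelta(hours=hours)


def make_admission(aid="A1", pid="P1", eid=None, start_h=0.0, end_h=48.0,
                   enc_start_h=None, age=5.0, sex="F"):
    return {
        "patient_id": pid, "admission_id": aid,
        "encounter_id": eid or f"E{aid}",
        "encounter_start": ts(enc_start_h if enc_start_h is not None
                              else start_h),
        "picu_start": ts(start_h), "picu_end": ts(end_h),
        "age_years": age, "sex": sex, "race": "White",
        "ethnicity": "Non-Hispanic", "insurance": "Private",
    }


@pytest.fixture
def admissions_factory():
    def make(rows):
        return pd.DataFrame([make_admission(**r) for r in rows])
    return make


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-patient synthetic cohort with a strong deterioration signal."""
    cfg = SyntheticConfig(n_patients=120, seed=7, event_prob=0.15,
                          effect_size=3.0)
    return generate_cohort(cfg)
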