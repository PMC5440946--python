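import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import predictbc as pb

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def model():
    return pb.default_model()


@pytest.fixture(scope="session")
def er_pos_patient():
    """The worked ER-positive patient used throughout the docs."""
    return pb.PatientRecord(age=40, size_mm=15, nodes=2, grade=2, screen=False, er="pos")


@pytest.fixture(scope="session")
def er_neg_patient():
    return pb.PatientRecord(age=50, size_mm=20, nodes=0, grade=3, screen=False, er="neg")


@pytest.fixture(scope="session")
def small_cohort(model):
    """A 400-patient mixed-ER cohort with outcomes (fast, reused read-only)."""
    return pb.simulate_cohort(400, model=model, seed=42)


@pytest.fixture(scope="session")
def patient_panel(model):
    """100 covariate rows spanning the supported ranges (no outcomes)."""
    return pb.sample_covariates(100, seed=2024)
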