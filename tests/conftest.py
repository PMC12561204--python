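import numpy as np
import pytest

from codmed.cohort_io import PatientRecord, TabularSchema


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_schema():
    return TabularSchema(
        numeric_fields=[("alb", 0.0, 60.0), ("crea", 0.0, 1500.0)],
        categorical_fields=[("stage", ["I", "II", "III"])],
    )


@pytest.fixture
def toy_records(toy_schema):
    return [
        PatientRecord("P1", {"alb": 35.0, "crea": 90.0, "stage": "I"},
                      [np.array([1.0, 3.0]), np.array([3.0, 1.0])], 0, "development"),
        PatientRecord("P2", {"alb": 28.0, "crea": 300.0, "stage": "III"},
                      [np.array([0.0, 0.0])], 1, "development"),
        PatientRecord("P3", {"alb": 41.0, "crea": 75.0, "stage": "I"},
                      [np.array([2.0, 2.0])], 0, "test"),
    ]
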