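import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from evpanel.panel_data import CohortDataset, PanelSchema, PatientRecord

settings.register_profile(
    "suite", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


def make_dataset(values, labels, llod=None, stages=None, mask=None) -> CohortDataset:
    """Small in-memory cohort for unit tests."""
    values = np.asarray(values, float)
    n, p = values.shape
    names = [f"M{j}" for j in range(p)]
    if llod is None:
        llod = np.full(p, 1e-6)
    schema = PanelSchema(names, dict(zip(names, np.asarray(llod, float))))
    if stages is None:
        stages = ["none" if l == 0 else "II" for l in labels]
    patients = [PatientRecord(f"p{i}", int(labels[i]), stages[i]) for i in range(n)]
    return CohortDataset(schema, patients, values, mask)


@pytest.fixture
def tiny_schema():
    return PanelSchema(["A", "B", "C"], {"A": 2.5, "B": 0.5, "C": 10.0})


@pytest.fixture(scope="session")
def study_cohort():
    """Study-scale synthetic cohort shared across read-only tests."""
    from evpanel.synthetic_cohort import default_study_config, generate_cohort

    return generate_cohort(default_study_config(seed=42))
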