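import numpy as np
import pandas as pd
import pytest

from surrocohort.claims_data import ClaimsBundle


def make_bundle(patients, diagnoses=(), prescriptions=()):
    """Build a validated bundle from row tuples.

    patients: (patient_id, sex, birth_year, enroll_start, enroll_end[, coverage, plan])
    diagnoses: (patient_id, claim_date, condition)
    prescriptions: (patient_id, drug_class, dispense_date, days_supplied)
    """
    prows = []
    for p in patients:
        p = tuple(p)
        if len(p) == 5:
            p = p + ("full", "PPO")
        prows.append(p)
    return ClaimsBundle(
        patients=pd.DataFrame(prows, columns=[
            "patient_id", "sex", "birth_year", "enroll_start", "enroll_end",
            "coverage", "plan"]),
        diagnoses=pd.DataFrame(list(diagnoses) or None, columns=[
            "patient_id", "claim_date", "condition"]),
        prescriptions=pd.DataFrame(list(prescriptions) or None, columns=[
            "patient_id", "drug_class", "dispense_date", "days_supplied"]),
    ).validate()


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def tiny_bundle():
    return make_bundle(
        patients=[("A", "F", 1950, 0, 1000), ("B", "M", 1940, 100, 2000)],
        diagnoses=[("A", 250, "RA"), ("B", 400, "RA")],
        prescriptions=[("A", "OS", 300, 30), ("B", "statin", 500, 30),
                       ("B", "OS", 600, 14)],
    )
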