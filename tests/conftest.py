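import math

import numpy as np
import pandas as pd
import pytest

import payrisk as pr


@pytest.fixture(scope="session")
def toy_maps():
    return pr.load_toy_maps()


@pytest.fixture(scope="session")
def small_bundle():
    """Hand-built 4-admission bundle exercising every filter boundary."""
    adm = pd.DataFrame({
        "admission_id": [1, 2, 3, 4],
        "patient_id": [11, 12, 13, 14],
        "hospital_id": [1, 1, 2, 2],
        "condition": ["HF", "HF", "HF", "AMI"],
        "age_years": [70, 64, 88, 75],
        "payment_30d": [12_000.0, 9_000.0, 20_000.0, 30_000.0],
        "died_30d": [0, 0, 1, 0],
    })
    dx = pd.DataFrame({
        "admission_id": [1, 1, 1, 1, 1],
        "code": ["D001", "D005", "D025", "D002", "D057"],
        "role": ["principal", "secondary", "secondary", "secondary",
                 "secondary"],
        "poa": ["Y", "Y", None, "missing", "N"],
        "window": ["index", "index", "history", "index", "index"],
    })
    # D002 is POA-exempt; D057 is unmapped; D025 -> CC07; admission 3 has
    # no diagnoses at all (a comorbidity-free stay)
    enr = pd.DataFrame({
        "patient_id": [11, 12, 13, 14],
        "prior_ffs_months": [24, 36, 12, 11],
    })
    return pr.ClaimsBundle(adm, dx, enr).validate()


@pytest.fixture(scope="session")
def hf_bundle_5k():
    """Mid-size single-condition bundle shared across expensive tests."""
    cfg = pr.SimConfig(
        n_patients=5_000, n_hospitals=40, seed=101,
        condition_mix={"HF": 1.0},
        code_catalog=pr.make_catalog(poa_all_yes=True),
        frac_short_enrollment=0.0, frac_under_65=0.0,
    )
    return pr.generate_bundle(cfg)


@pytest.fixture(scope="session")
def hf_cohort_5k(hf_bundle_5k):
    return pr.build_cohort(hf_bundle_5k, "HF")


def channel_truth(intercept=math.log(14_500.0)):
    """A truth with distinct index vs history effects on shared codes."""
    return {
        "HF": pr.ConditionTruth(
            intercept=intercept, age_75_84=0.05, age_85p=0.10,
            code_effects={
                ("D001", "index"): 0.45, ("D001", "history"): -0.10,
                ("D005", "index"): 0.05, ("D005", "history"): 0.35,
                ("D013", "index"): 0.40, ("D013", "history"): 0.00,
                ("D021", "index"): 0.00, ("D021", "history"): 0.30,
            },
        )
    }
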