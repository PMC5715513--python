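"""Shared fixtures: small random bundles and the deterministic flow fixture."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import phenoval as pv

STROKE_CODES = ["I639", "I633", "I619", "I609", "G458", "G459"]


def make_random_bundle(rng: np.random.Generator, n_patients: int = 25,
                       n_diagnoses: int = 60,
                       n_procedures: int = 40) -> pv.EmrBundle:
    """Small random bundle with colliding dates, for property tests.

    Dates are drawn from a narrow window so that same-day duplicates and
    near/far imaging offsets all actually occur.
    """
    ids = np.array([f"R{i:03d}" for i in range(n_patients)])
    base = pd.Timestamp("2010-01-01")
    reg = base + pd.to_timedelta(rng.integers(0, 30, n_patients), unit="D")
    patients = pd.DataFrame({
        "patient_id": ids,
        "birth_date": base - pd.Timedelta(days=365 * 50),
        "death_date": pd.NaT,
        "sex": rng.choice(["male", "female"], n_patients),
        "cancer_type": "other",
        "cancer_stage": "unknown",
        "registration_date": reg,
    })
    patients["death_date"] = pd.to_datetime(patients["death_date"])
    diagnoses = pd.DataFrame({
        "record_id": [f"d{i:04d}" for i in range(n_diagnoses)],
        "patient_id": rng.choice(ids, n_diagnoses),
        "code": rng.choice(STROKE_CODES, n_diagnoses),
        "registration_date": base + pd.to_timedelta(
            rng.integers(0, 12, n_diagnoses), unit="D"),
        "certainty": rng.choice(["definite", "suspected"], n_diagnoses,
                                p=[0.75, 0.25]),
        "position": rng.choice(["primary", "secondary", "other"], n_diagnoses),
        "department": "neurology",
    })
    procedures = pd.DataFrame({
        "record_id": [f"p{i:04d}" for i in range(n_procedures)],
        "patient_id": rng.choice(ids, n_procedures),
        "modality": rng.choice(["CT", "MRI"], n_procedures),
        "order_date": base + pd.to_timedelta(
            rng.integers(-40, 60, n_procedures), unit="D"),
    })
    return pv.EmrBundle(patients, diagnoses, procedures)


@pytest.fixture(scope="session")
def flow_fixture():
    """The shipped exact-count fixture bundle and its truth table."""
    return pv.generate_fixture(pv.load_fixture_spec())


@pytest.fixture(scope="session")
def calibrated_cohort():
    """One calibrated stochastic cohort, reused across tests."""
    return pv.generate_cohort(pv.load_scenario(seed=20071231))


@pytest.fixture(scope="session")
def calibrated_pipeline(calibrated_cohort):
    """Cleaned cohort, deduped stroke records and arm assignments."""
    bundle, truth = calibrated_cohort
    sets = pv.default_code_sets()
    stroke = pv.extract_codes(bundle.diagnoses, sets["stroke"])
    deduped = pv.dedup_diagnoses(stroke)
    assignments = pv.classify_arms(deduped, bundle.procedures)
    return bundle, truth, deduped, assignments
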