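"""Shared fixtures: hand-buildable registries and default model parameters."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pexaudit.registry import Registry

PATIENT_DEFAULTS = {
    "race": "White", "ethnicity": "NonHispanic", "sex": "female",
    "f508del": "homozygous", "baseline_age": 10.0,
    "insurance_private": True, "smoker": False,
    "smoking_household": False, "secondhand_smoke": False,
    "primary_road_density": 0.002, "secondary_road_density": 0.005,
    "deprivation_index": 0.35, "greenspace_fraction": 0.8,
    "distance_to_center": 50.0, "drive_time_to_center": 45.0,
}

ENCOUNTER_DEFAULTS = {
    "on_iv": False, "medicaid": False, "cfrd": False,
    "pa_positive": False, "mrsa_positive": False,
}


def make_patient(patient_id: str, **overrides) -> dict:
    row = {"patient_id": patient_id, **PATIENT_DEFAULTS}
    row.update(overrides)
    return row


def make_encounter(patient_id: str, t: float, fev1_pp: float, **overrides) -> dict:
    row = {"patient_id": patient_id, "t": t, "age": 10.0 + t / 365.25,
           "fev1_pp": fev1_pp, **ENCOUNTER_DEFAULTS}
    row.update(overrides)
    return row


def make_registry(patients: list[dict], encounters: list[dict]) -> Registry:
    return Registry(patients=pd.DataFrame(patients),
                    encounters=pd.DataFrame(encounters))


@pytest.fixture
def two_patient_registry() -> Registry:
    patients = [make_patient("P1"), make_patient("P2", race="Black", sex="male")]
    encounters = [
        make_encounter("P1", 0.0, 95.0),
        make_encounter("P1", 90.0, 92.0),
        make_encounter("P1", 180.0, 88.0),
        make_encounter("P2", 0.0, 80.0),
        make_encounter("P2", 120.0, 78.5),
    ]
    return make_registry(patients, encounters)


def random_registry(rng: np.random.Generator, n_patients: int = 10,
                    max_visits: int = 12) -> Registry:
    """A small structurally valid registry with random (not model-based) values."""
    patients, encounters = [], []
    races = ["White", "Black", "Other"]
    for i in range(n_patients):
        pid = f"R{i:03d}"
        patients.append(make_patient(
            pid, race=races[rng.integers(3)],
            ethnicity=["Hispanic", "NonHispanic", "Unknown"][rng.integers(3)],
            sex=["female", "male"][rng.integers(2)],
            baseline_age=float(6 + rng.random() * 30),
            deprivation_index=float(rng.random()),
            greenspace_fraction=float(rng.random()),
        ))
        n_vis = int(rng.integers(1, max_visits + 1))
        times = np.sort(rng.choice(np.arange(0, 2000), size=n_vis, replace=False)).astype(float)
        for t in times:
            encounters.append(make_encounter(
                pid, float(t), float(40 + rng.random() * 80),
                on_iv=bool(rng.random() < 0.1)))
    return make_registry(patients, encounters)
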