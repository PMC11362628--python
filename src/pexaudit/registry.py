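"""Registry data model: patient and encounter tables, validation, CSV I/O.

A registry couples a static patient table (demographics, genotype, place-based
covariates) with a longitudinal encounter table (one row per clinical visit:
time, FEV1 % predicted, IV-antibiotic flag, time-varying covariates).  Both
are held as :class:`pandas.DataFrame` with a fixed, documented schema; all
downstream stages (labeling, model fitting, fairness evaluation, screening)
consume this container.

Time convention: ``t`` is days since the patient's own first encounter, as a
float.  One month is 30.4375 days and one year 365.25 days throughout the
package, so window arithmetic is exact and testable.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25

RACE_LEVELS = ("White", "Black", "Other")
ETHNICITY_LEVELS = ("Hispanic", "NonHispanic", "Unknown")
SEX_LEVELS = ("female", "male")
F508DEL_LEVELS = ("homozygous", "heterozygous", "neither_unknown")

#: patient table schema: column -> (kind, allowed levels or None)
PATIENT_SCHEMA = {
    "patient_id": "string",
    "race": RACE_LEVELS,
    "ethnicity": ETHNICITY_LEVELS,
    "sex": SEX_LEVELS,
    "f508del": F508DEL_LEVELS,
    "baseline_age": "float",
    "insurance_private": "bool",
    "smoker": "bool",
    "smoking_household": "bool",
    "secondhand_smoke": "bool",
    "primary_road_density": "float",
    "secondary_road_density": "float",
    "deprivation_index": "float",
    "greenspace_fraction": "float",
    "distance_to_center": "float",
    "drive_time_to_center": "float",
}

ENCOUNTER_SCHEMA = {
    "patient_id": "string",
    "t": "float",
    "age": "float",
    "fev1_pp": "float",
    "on_iv": "bool",
    "medicaid": "bool",
    "cfrd": "bool",
    "pa_positive": "bool",
    "mrsa_positive": "bool",
}

_PATIENT_BOOLS = [c for c, k in PATIENT_SCHEMA.items() if k == "bool"]
_ENCOUNTER_BOOLS = [c for c, k in ENCOUNTER_SCHEMA.items() if k == "bool"]


class RegistryError(Exception):
    """Base class for registry validation failures."""


class SchemaError(RegistryError):
    """A required column is missing or has an unexpected type/level."""


class IntegrityError(RegistryError):
    """Referential integrity between patients and encounters is broken."""


class ValidationError(RegistryError):
    """A value-level invariant is violated (ranges, monotone times, duplicates)."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (half-up), as in printed clinical tables.

    Python's built-in ``round`` is banker's rounding; percentage tables in the
    clinical literature round 0.05 up, so summaries use this helper.
    """
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass
class Registry:
    """Validated pair of patient and encounter tables.

    Invariants (enforced by :meth:`validate`):

    * every encounter's ``patient_id`` exists in the patient table;
    * every patient has at least one encounter;
    * within a patient, encounter times are strictly increasing and start >= 0;
    * categorical columns take only their documented levels;
    * ``fev1_pp`` in (0, 150], ``baseline_age`` >= 6, densities/fractions in range.
    """

    patients: pd.DataFrame
    encounters: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        _check_columns(self.patients, PATIENT_SCHEMA, "patients")
        _check_columns(self.encounters, ENCOUNTER_SCHEMA, "encounters")

        pat = self.patients
        enc = self.encounters

        if pat["patient_id"].duplicated().any():
            dup = pat.loc[pat["patient_id"].duplicated(), "patient_id"].iloc[0]
            raise ValidationError(f"duplicate patient_id {dup!r} in patient table")

        for col, kind in PATIENT_SCHEMA.items():
            if isinstance(kind, tuple):
                bad = set(pat[col].unique()) - set(kind)
                if bad:
                    raise SchemaError(
                        f"patients.{col}: unexpected level(s) {sorted(bad)!r}; "
                        f"allowed {list(kind)}"
                    )

        if (pat["baseline_age"] < 6).any():
            raise ValidationError("baseline_age below 6 years (cohort is aged 6 and above)")
        for col in ("primary_road_density", "secondary_road_density",
                    "distance_to_center", "drive_time_to_center"):
            if (pat[col] < 0).any():
                raise ValidationError(f"patients.{col} must be >= 0")
        for col in ("deprivation_index", "greenspace_fraction"):
            if ((pat[col] < 0) | (pat[col] > 1)).any():
                raise ValidationError(f"patients.{col} must lie in [0, 1]")

        known = set(pat["patient_id"])
        orphan = set(enc["patient_id"]) - known
        if orphan:
            raise IntegrityError(
                f"encounters reference unknown patient_id(s): {sorted(orphan)[:5]!r}"
            )
        missing = known - set(enc["patient_id"])
        if missing:
            raise IntegrityError(
                f"patient(s) with no encounters: {sorted(missing)[:5]!r}"
            )

        if ((enc["fev1_pp"] <= 0) | (enc["fev1_pp"] > 150)).any():
            raise ValidationError("fev1_pp must lie in (0, 150]")
        if (enc["t"] < 0).any():
            raise ValidationError("encounter t must be >= 0")

        # strictly increasing times within each patient (also catches duplicates)
        for pid, grp in enc.groupby("patient_id", sort=False):
            t = grp["t"].to_numpy()
            if not np.all(np.diff(np.sort(t)) > 0):
                raise ValidationError(
                    f"patient {pid!r}: encounter times not strictly increasing "
                    "(duplicate or non-monotone t)"
                )

    # -- convenience --------------------------------------------------------

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_encounters(self) -> int:
        return len(self.encounters)

    def sorted_encounters(self) -> pd.DataFrame:
        """Encounters sorted by (patient_id, t)."""
        return self.encounters.sort_values(["patient_id", "t"], kind="mergesort").reset_index(drop=True)

    def patient_encounters(self, patient_id: str) -> pd.DataFrame:
        grp = self.encounters[self.encounters["patient_id"] == patient_id]
        return grp.sort_values("t").reset_index(drop=True)


def _check_columns(df: pd.DataFrame, schema: dict, name: str) -> None:
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table missing column(s): {missing}")


# -- I/O --------------------------------------------------------------------

def read_registry(patients_path: str | Path, encounters_path: str | Path) -> Registry:
    """Read and validate a registry from two CSV files.

    The CSV dialect is comma-separated UTF-8 with a header row; booleans are
    serialized as 0/1 and missing values as the empty string.  Encounters are
    returned sorted by ``(patient_id, t)``.
    """
    patients_path, encounters_path = Path(patients_path), Path(encounters_path)
    for p in (patients_path, encounters_path):
        if not p.exists():
            raise FileNotFoundError(p)
    pat = pd.read_csv(patients_path, dtype={"patient_id": str})
    enc = pd.read_csv(encounters_path, dtype={"patient_id": str})
    _check_columns(pat, PATIENT_SCHEMA, "patients")
    _check_columns(enc, ENCOUNTER_SCHEMA, "encounters")
    for col in _PATIENT_BOOLS:
        pat[col] = pat[col].astype(int).astype(bool)
    for col in _ENCOUNTER_BOOLS:
        enc[col] = enc[col].astype(int).astype(bool)
    enc = enc.sort_values(["patient_id", "t"], kind="mergesort").reset_index(drop=True)
    return Registry(patients=pat.reset_index(drop=True), encounters=enc)


def write_registry(registry: Registry, out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``patients.csv`` and ``encounters.csv``; round-trips exactly.

    Floats are written with :func:`repr` precision so ``read_registry`` after
    ``write_registry`` reproduces every field bit-for-bit.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ppath, epath = out_dir / "patients.csv", out_dir / "encounters.csv"
    pat = registry.patients.copy()
    enc = registry.sorted_encounters()
    for col in _PATIENT_BOOLS:
        pat[col] = pat[col].astype(int)
    for col in _ENCOUNTER_BOOLS:
        enc[col] = enc[col].astype(int)
    pat.to_csv(ppath, index=False, float_format=None)
    enc.to_csv(epath, index=False, float_format=None)
    return ppath, epath


# -- cohort summary ---------------------------------------------------------

def cohort_summary(registry: Registry) -> pd.DataFrame:
    """Counts and percentages of each demographic partition of the cohort.

    Returns one row per (variable, level) with columns ``variable``, ``level``,
    ``n`` and ``pct``; ``pct`` is 100*n/total rounded half-up to one decimal,
    the convention of printed registry tables.  Within each variable the
    levels form a complete partition, so the percentages sum to 100 up to
    rounding (within 0.2).

    Also reports, for each race, the percentage with unknown ethnicity, using
    the within-race denominator (``ethnicity_unknown_by_race`` rows).
    """
    if registry.n_patients == 0:
        raise ValidationError("cohort_summary of an empty registry")
    pat = registry.patients
    total = len(pat)
    rows: list[dict] = []
    for var, levels in (("race", RACE_LEVELS), ("ethnicity", ETHNICITY_LEVELS),
                        ("f508del", F508DEL_LEVELS), ("sex", SEX_LEVELS)):
        counts = pat[var].value_counts()
        for level in levels:
            n = int(counts.get(level, 0))
            rows.append({"variable": var, "level": level, "n": n,
                         "pct": round_half_up(100.0 * n / total, 1)})
    for race in RACE_LEVELS:
        sub = pat[pat["race"] == race]
        if len(sub) == 0:
            continue
        n_unknown = int((sub["ethnicity"] == "Unknown").sum())
        rows.append({"variable": "ethnicity_unknown_by_race", "level": race,
                     "n": n_unknown,
                     "pct": round_half_up(100.0 * n_unknown / len(sub), 1)})
    return pd.DataFrame(rows, columns=["variable", "level", "n", "pct"])
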