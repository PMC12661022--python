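"""Cohort table container and delimited-file round-trip.

An EHR-style cohort is represented by three tab-delimited tables (patients,
diagnosis events, medication events) plus an optional ground-truth table that
only exists for synthetic cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

PATIENT_COLUMNS = [
    "patient_id",
    "sex",
    "group",
    "age_last_visit",
    "record_length",
    "n_encounters",
    "n_diagnoses",
    "record_density",
]
DIAGNOSIS_COLUMNS = ["patient_id", "icd10cm", "date"]
MEDICATION_COLUMNS = ["patient_id", "drug_name", "date"]
TRUTH_COLUMNS = ["patient_id", "true_case"]


class CohortError(ValueError):
    """Raised when cohort tables violate their structural invariants."""


@dataclass
class CohortTables:
    """The three raw cohort tables, plus optional synthetic ground truth.

    ``patients`` carries one row per patient with demographics and the
    utilization covariates (age at last visit in years, record length in
    years, encounter and diagnosis counts, record density in encounters per
    year). ``diagnoses`` and ``medications`` are long event tables keyed by
    ``patient_id`` with ISO-8601 dates.
    """

    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    medications: pd.DataFrame
    truth: pd.DataFrame | None = None

    def validate(self) -> None:
        pat = self.patients
        if pat["patient_id"].duplicated().any():
            raise CohortError("duplicate patient_id in patients table")
        known = set(pat["patient_id"])
        for name, tab in (("diagnoses", self.diagnoses), ("medications", self.medications)):
            if not set(tab["patient_id"]).issubset(known):
                raise CohortError(f"{name} references unknown patient_id")
        if self.truth is not None and not set(self.truth["patient_id"]).issubset(known):
            raise CohortError("truth references unknown patient_id")


def write_cohort(tables: CohortTables, directory: str | Path) -> dict[str, Path]:
    """Write a cohort as tab-delimited UTF-8 files with header rows.

    Emits ``patients.tsv``, ``diagnoses.tsv``, ``medications.tsv`` and, when
    ground truth is present, ``truth.tsv``. Files round-trip losslessly
    through :func:`read_cohort` and are byte-identical across repeated writes
    of the same tables.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    frames = {
        "patients": tables.patients[PATIENT_COLUMNS],
        "diagnoses": tables.diagnoses[DIAGNOSIS_COLUMNS],
        "medications": tables.medications[MEDICATION_COLUMNS],
    }
    if tables.truth is not None:
        frames["truth"] = tables.truth[TRUTH_COLUMNS]
    for name, frame in frames.items():
        path = directory / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
        written[name] = path
    return written


def read_cohort(directory: str | Path) -> CohortTables:
    """Read a cohort written by :func:`write_cohort`."""
    directory = Path(directory)

    def _read(name: str, columns: list[str], required: bool = True) -> pd.DataFrame | None:
        path = directory / f"{name}.tsv"
        if not path.exists():
            if required:
                raise FileNotFoundError(path)
            return None
        frame = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "icd10cm": str})
        missing = [c for c in columns if c not in frame.columns]
        if missing:
            raise CohortError(f"{name}.tsv missing columns {missing}")
        return frame[columns]

    tables = CohortTables(
        patients=_read("patients", PATIENT_COLUMNS),
        diagnoses=_read("diagnoses", DIAGNOSIS_COLUMNS),
        medications=_read("medications", MEDICATION_COLUMNS),
        truth=_read("truth", TRUTH_COLUMNS, required=False),
    )
    if tables.truth is not None:
        tables.truth = tables.truth.assign(true_case=tables.truth["true_case"].astype(int))
    tables.validate()
    return tables
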