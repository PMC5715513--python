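"""Typed containers and strict CSV I/O for the three EMR tables.

The pipeline operates on three flat tables — a patient registry, diagnosis
code registrations, and imaging procedure orders — held as pandas DataFrames
inside an :class:`EmrBundle`.  Loading is strict: every row must parse, dates
are day-resolution ISO-8601, ICD-10 codes are normalized (uppercase, dot
removed), and enumerated fields admit only their documented values.  A bundle
written with :func:`write_bundle` reloads to an identical bundle.

Schemas (exact CSV headers)
---------------------------
patients.csv
    patient_id, birth_date, death_date, sex, cancer_type, cancer_stage,
    registration_date  (empty death_date means alive)
diagnoses.csv
    record_id, patient_id, code, registration_date, certainty, position,
    department
procedures.csv
    record_id, patient_id, modality, order_date
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

from .code_sets import normalize_code
from .errors import (
    DateParseError,
    EnumValueError,
    MissingColumnError,
    ReferentialIntegrityError,
)

SEXES = ("male", "female")
CANCER_STAGES = ("0", "I", "II", "III", "IV", "unknown")
CERTAINTIES = ("definite", "suspected")
POSITIONS = ("primary", "secondary", "other")
MODALITIES = ("CT", "MRI")

PATIENT_COLUMNS = [
    "patient_id", "birth_date", "death_date", "sex",
    "cancer_type", "cancer_stage", "registration_date",
]
DIAGNOSIS_COLUMNS = [
    "record_id", "patient_id", "code", "registration_date",
    "certainty", "position", "department",
]
PROCEDURE_COLUMNS = ["record_id", "patient_id", "modality", "order_date"]

_DATE_COLUMNS = {
    "patients": ["birth_date", "death_date", "registration_date"],
    "diagnoses": ["registration_date"],
    "procedures": ["order_date"],
}
_OPTIONAL_DATES = {"death_date"}
_ENUM_COLUMNS = {
    "patients": {"sex": SEXES, "cancer_stage": CANCER_STAGES},
    "diagnoses": {"certainty": CERTAINTIES, "position": POSITIONS},
    "procedures": {"modality": MODALITIES},
}


@dataclass
class EmrBundle:
    """The three EMR tables, schema-validated and mutually consistent."""

    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    procedures: pd.DataFrame

    def __post_init__(self):
        self.patients = self.patients.reset_index(drop=True)
        self.diagnoses = self.diagnoses.reset_index(drop=True)
        self.procedures = self.procedures.reset_index(drop=True)

    def check_referential_integrity(self) -> None:
        """Every patient_id in diagnoses/procedures must exist in patients."""
        known = set(self.patients["patient_id"])
        for name, table in (("diagnoses", self.diagnoses),
                            ("procedures", self.procedures)):
            orphans = sorted(set(table["patient_id"]) - known)
            if orphans:
                raise ReferentialIntegrityError(name, orphans)

    def equals(self, other: "EmrBundle") -> bool:
        return (
            self.patients.equals(other.patients)
            and self.diagnoses.equals(other.diagnoses)
            and self.procedures.equals(other.procedures)
        )


@dataclass
class RowError:
    """One rejected row, reported instead of silently dropped."""

    table: str
    row: int  # 0-based data row in the source file
    message: str


@dataclass
class LoadReport:
    """Outcome of a tolerant load: accepted rows plus per-row rejections."""

    bundle: EmrBundle
    errors: list[RowError] = field(default_factory=list)


def _require_columns(df: pd.DataFrame, table: str, columns: list[str]) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise MissingColumnError(table, missing)


def _parse_table(df: pd.DataFrame, table: str, columns: list[str],
                 collect: list[RowError] | None) -> pd.DataFrame:
    """Validate and coerce one raw string table.

    With ``collect`` supplied, bad rows are appended there and dropped;
    otherwise the first bad row raises.
    """
    _require_columns(df, table, columns)
    df = df[columns].copy()
    bad = pd.Series(False, index=df.index)

    for col in _DATE_COLUMNS[table]:
        raw = df[col].astype("string").str.strip()
        if col in _OPTIONAL_DATES:
            raw = raw.replace("", pd.NA)
        parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
        failed = parsed.isna() & raw.notna()
        if col not in _OPTIONAL_DATES:
            failed = failed | raw.isna()
        for idx in df.index[failed & ~bad]:
            err = DateParseError(table, int(idx), col, df.at[idx, col])
            if collect is None:
                raise err
            collect.append(RowError(table, int(idx), str(err)))
        bad |= failed
        df[col] = parsed

    for col, allowed in _ENUM_COLUMNS[table].items():
        values = df[col].astype("string").str.strip()
        failed = ~values.isin(allowed)
        for idx in df.index[failed & ~bad]:
            err = EnumValueError(table, int(idx), col, df.at[idx, col], allowed)
            if collect is None:
                raise err
            collect.append(RowError(table, int(idx), str(err)))
        bad |= failed
        df[col] = values

    if table == "diagnoses":
        normalized = []
        for idx, raw in df["code"].items():
            if bad.at[idx]:
                normalized.append("")
                continue
            try:
                normalized.append(normalize_code(raw))
            except Exception as err:
                if collect is None:
                    raise
                collect.append(RowError(table, int(idx), f"row {idx}: {err}"))
                bad.at[idx] = True
                normalized.append("")
        df["code"] = normalized

    for col in df.columns:
        if df[col].dtype == object or str(df[col].dtype) == "string":
            df[col] = df[col].astype("string").fillna("").astype(str)

    return df.loc[~bad].reset_index(drop=True)


def _assign_record_ids(df: pd.DataFrame, prefix: str) -> pd.DataFrame:
    """Fill empty record_id fields from file order (stable dedup tie-break)."""
    blank = df["record_id"].astype(str).str.strip() == ""
    if blank.any():
        df = df.copy()
        df.loc[blank, "record_id"] = [
            f"{prefix}{i:07d}" for i in df.index[blank]
        ]
    return df


def _read_csv(path: str | os.PathLike, table: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(f"{table} file not found: {path}")
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def load_bundle(patients_path, diagnoses_path, procedures_path,
                *, on_error: str = "raise") -> EmrBundle | LoadReport:
    """Load and validate the three CSVs into an :class:`EmrBundle`.

    Parameters
    ----------
    on_error
        ``"raise"`` (default) aborts on the first invalid row with a named
        error carrying the row number.  ``"collect"`` returns a
        :class:`LoadReport` whose errors list accounts for every rejected
        row, so that rows-in equals rows-accepted plus rows-reported.
    """
    if on_error not in ("raise", "collect"):
        raise ValueError("on_error must be 'raise' or 'collect'")
    collect: list[RowError] | None = [] if on_error == "collect" else None

    patients = _parse_table(_read_csv(patients_path, "patients"),
                            "patients", PATIENT_COLUMNS, collect)
    diagnoses = _parse_table(_read_csv(diagnoses_path, "diagnoses"),
                             "diagnoses", DIAGNOSIS_COLUMNS, collect)
    procedures = _parse_table(_read_csv(procedures_path, "procedures"),
                              "procedures", PROCEDURE_COLUMNS, collect)
    diagnoses = _assign_record_ids(diagnoses, "D")
    procedures = _assign_record_ids(procedures, "P")

    bundle = EmrBundle(patients, diagnoses, procedures)
    if collect is None:
        bundle.check_referential_integrity()
        return bundle
    return LoadReport(bundle, collect)


def _format_dates(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    out = df.copy()
    for col in columns:
        out[col] = out[col].dt.strftime("%Y-%m-%d").fillna("")
    return out


def write_bundle(bundle: EmrBundle, directory: str | os.PathLike) -> dict[str, str]:
    """Write the bundle as three CSVs; inverse of :func:`load_bundle`.

    Output is byte-stable: fixed column order, ISO dates, empty string for
    an absent death date.
    """
    os.makedirs(directory, exist_ok=True)
    paths = {}
    tables = {
        "patients": _format_dates(bundle.patients, _DATE_COLUMNS["patients"]),
        "diagnoses": _format_dates(bundle.diagnoses, _DATE_COLUMNS["diagnoses"]),
        "procedures": _format_dates(bundle.procedures, _DATE_COLUMNS["procedures"]),
    }
    for name, df in tables.items():
        path = os.path.join(directory, f"{name}.csv")
        df.to_csv(path, index=False)
        paths[name] = path
    return paths
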