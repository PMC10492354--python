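"""Reading encounter records, the multimorbidity inclusion filter, and the
patient x specialty involvement matrix.

The input is a long-format table with one row per patient-specialty-diagnosis
combination, mirroring hospital billing extracts (Dutch DTC records): each
row carries the treating specialty, the diagnosis (code, group, type) and
care-activity counts (outpatient visits, ED visits, inpatient days).

The cohort of interest is adult multimorbid patients: age >= 18 with at
least two distinct chronic and/or oncological diagnoses for which outpatient
care was received.  The clustering feature space is the binary matrix
recording which specialties were involved in each retained patient's care.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ParseError",
    "IntegrityError",
    "ENCOUNTER_COLUMNS",
    "DIAGNOSIS_TYPES",
    "CohortMatrix",
    "read_encounters",
    "validate_encounters",
    "apply_inclusion_filter",
    "build_involvement_matrix",
    "load_diagnosis_group_map",
]


class SchemaError(ValueError):
    """A required column is missing or a categorical value is out of range."""


class ParseError(ValueError):
    """A cell failed numeric/type validation; the message cites the rows."""


class IntegrityError(ValueError):
    """Internally inconsistent data (conflicting ages, duplicate codes...)."""


ENCOUNTER_COLUMNS = (
    "patient_id", "age_years", "sex", "specialty", "diagnosis_code",
    "diagnosis_group", "diagnosis_type", "outpatient_visits", "ed_visits",
    "inpatient_days",
)
DIAGNOSIS_TYPES = frozenset({"acute", "chronic", "elective", "oncological", "other"})
SEXES = frozenset({"female", "male"})
_COUNT_COLUMNS = ("outpatient_visits", "ed_visits", "inpatient_days")


def _check_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): "
                          + ", ".join(missing))


def _coerce_counts(df: pd.DataFrame, col: str) -> pd.Series:
    values = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[values.isna()].tolist()
    if bad:
        raise ParseError(f"non-numeric value in column '{col}' at row(s) {bad}")
    if (values < 0).any():
        bad = df.index[values < 0].tolist()
        raise ParseError(f"negative count in column '{col}' at row(s) {bad}")
    return values.astype(int)


def validate_encounters(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize an in-memory encounter table.

    Returns a copy with numeric columns coerced; raises :class:`SchemaError`,
    :class:`ParseError` or :class:`IntegrityError` with offending rows named.
    """
    _check_columns(df, ENCOUNTER_COLUMNS, "encounter table")
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    df["specialty"] = df["specialty"].astype(str)
    empty = df.index[(df["patient_id"].str.len() == 0)
                     | (df["specialty"].str.len() == 0)].tolist()
    if empty:
        raise ParseError(f"empty patient_id or specialty at row(s) {empty}")

    ages = pd.to_numeric(df["age_years"], errors="coerce")
    bad = df.index[ages.isna() | (ages < 0)].tolist()
    if bad:
        raise ParseError(f"invalid age_years at row(s) {bad}")
    df["age_years"] = ages.astype(float)

    bad = df.index[~df["sex"].isin(SEXES)].tolist()
    if bad:
        raise SchemaError(f"sex must be one of {sorted(SEXES)}; bad row(s) {bad}")
    bad = df.index[~df["diagnosis_type"].isin(DIAGNOSIS_TYPES)].tolist()
    if bad:
        raise SchemaError(f"diagnosis_type must be one of "
                          f"{sorted(DIAGNOSIS_TYPES)}; bad row(s) {bad}")
    for col in _COUNT_COLUMNS:
        df[col] = _coerce_counts(df, col)

    # age and sex are study-year constants per patient
    for col in ("age_years", "sex"):
        n_distinct = df.groupby("patient_id")[col].nunique()
        conflicted = n_distinct[n_distinct > 1].index.tolist()
        if conflicted:
            raise IntegrityError(
                f"conflicting {col} values for patient(s) {conflicted}")
    return df


def read_encounters(path, *, delimiter: str = ",") -> pd.DataFrame:
    """Read and validate an encounter file (delimited text, UTF-8, header)."""
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False,
                     encoding="utf-8")
    return validate_encounters(df)


def load_diagnosis_group_map(path, *, delimiter: str = ",") -> dict:
    """Load a diagnosis_code -> (diagnosis_group, diagnosis_type) mapping.

    The file must have a header with columns diagnosis_code, diagnosis_group,
    diagnosis_type; a code mapping to two different targets is an
    :class:`IntegrityError`.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False,
                     encoding="utf-8")
    _check_columns(df, ("diagnosis_code", "diagnosis_group", "diagnosis_type"),
                   "diagnosis map")
    bad = df.index[~df["diagnosis_type"].isin(DIAGNOSIS_TYPES)].tolist()
    if bad:
        raise SchemaError(f"unknown diagnosis_type label at row(s) {bad}")
    mapping: dict = {}
    for _, row in df.iterrows():
        code = row["diagnosis_code"]
        target = (row["diagnosis_group"], row["diagnosis_type"])
        if code in mapping and mapping[code] != target:
            raise IntegrityError(
                f"diagnosis_code '{code}' maps to conflicting targets "
                f"{mapping[code]} and {target}")
        mapping[code] = target
    return mapping


def apply_inclusion_filter(table: pd.DataFrame, *, min_age: float = 18,
                           require_outpatient_visit: bool = True,
                           count_level: str = "diagnosis_code") -> pd.DataFrame:
    """Retain multimorbid adults: age >= min_age and >= 2 distinct chronic
    and/or oncological diagnoses with outpatient care.

    Counting >= 2 over the union of chronic and oncological diagnoses is
    equivalent to the three disjuncts (two chronic; two oncological; one of
    each), since each diagnosis has exactly one type.  "Received outpatient
    care for" a diagnosis is operationalized as that diagnosis having at
    least one recorded outpatient visit (disable with
    ``require_outpatient_visit=False``).  Diagnoses are counted as distinct
    values of ``count_level`` ("diagnosis_code" or "diagnosis_group").

    All rows of retained patients are kept, including acute/elective/other
    rows.  Idempotent; an empty result is valid.
    """
    if count_level not in ("diagnosis_code", "diagnosis_group"):
        raise ValueError("count_level must be 'diagnosis_code' or 'diagnosis_group'")
    qualifying = table[table["diagnosis_type"].isin(("chronic", "oncological"))]
    if require_outpatient_visit:
        qualifying = qualifying[qualifying["outpatient_visits"] >= 1]
    # distinct chronic diagnoses + distinct oncological diagnoses
    n_dx = (qualifying.groupby(["patient_id", "diagnosis_type"])[count_level]
            .nunique().groupby("patient_id").sum())
    age = table.groupby("patient_id")["age_years"].first()
    eligible = age.index[(age >= min_age)
                         & (n_dx.reindex(age.index, fill_value=0) >= 2)]
    return table[table["patient_id"].isin(eligible)].reset_index(drop=True)


@dataclass
class CohortMatrix:
    """Binary patient x specialty involvement matrix.

    ``values[i, j] == 1`` iff patient ``patient_ids[i]`` had at least one
    encounter row with specialty ``specialty_names[j]``.  Rows are sorted by
    patient_id and columns lexicographically by specialty name.
    """

    patient_ids: list
    specialty_names: list
    values: np.ndarray

    def __post_init__(self):
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise IntegrityError("duplicate patient_ids in CohortMatrix")
        if len(set(self.specialty_names)) != len(self.specialty_names):
            raise IntegrityError("duplicate specialty names in CohortMatrix")
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.patient_ids), len(self.specialty_names)):
            raise ValueError("values shape does not match id/name lists")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("involvement matrix entries must be 0/1")
        if self.values.shape[0] and not self.values.any(axis=1).all():
            raise IntegrityError("a patient with no involved specialty cannot "
                                 "exist after inclusion filtering")

    @property
    def shape(self):
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.patient_ids,
                                                        name="patient_id"),
                            columns=self.specialty_names)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "CohortMatrix":
        df = pd.read_csv(path, index_col="patient_id")
        return cls(patient_ids=[str(i) for i in df.index],
                   specialty_names=list(df.columns),
                   values=df.to_numpy(dtype=np.int8))


def build_involvement_matrix(table: pd.DataFrame,
                             min_prevalence: float = 0.0) -> CohortMatrix:
    """Binary involvement matrix from an (already filtered) encounter table.

    ``min_prevalence`` optionally drops specialties involved in fewer than
    that fraction of patients (default 0: keep every observed specialty).
    """
    if len(table) == 0:
        raise ValueError("no patients after filtering")
    crosstab = (table.groupby(["patient_id", "specialty"]).size()
                .unstack(fill_value=0) > 0).astype(np.int8)
    crosstab = crosstab.sort_index(axis=0).sort_index(axis=1)
    if min_prevalence > 0:
        keep = crosstab.columns[crosstab.mean(axis=0) >= min_prevalence]
        crosstab = crosstab[keep]
    return CohortMatrix(patient_ids=[str(i) for i in crosstab.index],
                        specialty_names=list(crosstab.columns),
                        values=crosstab.to_numpy())
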