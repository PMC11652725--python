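"""Cohort variable schema, CSV I/O, validation, and the standard transforms.

The analysis operates on a per-participant rectangular table of demographic,
smoking, spirometry, COPD-severity, scanner and CT-derived airway variables.
All airway metrics (TAC, TACp, WT) and lung size are analysed on the natural
log scale; COPD severity is an ordinal 0-3 code (preserved lung function,
mild, moderate, severe) that can also be expanded into three indicator
columns against the preserved reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import SchemaError

ROLES = ("demographic", "exposure", "severity", "technical", "ct_outcome", "spirometry")
SCALES = ("binary", "ordinal", "continuous")

SEVERITY_LEVELS = (0, 1, 2, 3)
SEVERITY_GROUPS = ("preserved", "mild", "moderate", "severe")
#: dummy columns appended by :func:`encode_severity`, in severity order 1..3
SEVERITY_DUMMIES = ("sev_mild", "sev_moderate", "sev_severe")

#: natural-scale column -> log column appended by :func:`apply_log_transforms`
LOG_COLUMNS = {
    "tac": "log_tac",
    "tac_p": "log_tac_p",
    "wt": "log_wt",
    "lung_size": "log_lung_size",
}


@dataclass(frozen=True)
class VariableSchema:
    """Declaration of a single analysis variable."""

    name: str
    role: str
    scale: str
    log_transformed: bool = False

    def __post_init__(self):
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r} for variable {self.name!r}")
        if self.scale not in SCALES:
            raise SchemaError(f"unknown scale {self.scale!r} for variable {self.name!r}")


#: the canonical cohort schema (column order of the interchange CSV)
COHORT_SCHEMA: tuple[VariableSchema, ...] = (
    VariableSchema("age", "demographic", "continuous"),
    VariableSchema("sex", "demographic", "binary"),  # 1 = male, 0 = female
    VariableSchema("bmi", "demographic", "continuous"),
    VariableSchema("lung_size", "demographic", "continuous"),
    VariableSchema("pack_years", "exposure", "continuous"),
    VariableSchema("fev1_fvc", "spirometry", "continuous"),
    VariableSchema("fev1_pct_pred", "spirometry", "continuous"),
    VariableSchema("severity", "severity", "ordinal"),
    VariableSchema("scanner", "technical", "binary"),  # 1 = Flash, 0 = Force
    VariableSchema("tac", "ct_outcome", "continuous"),
    VariableSchema("tac_p", "ct_outcome", "continuous"),
    VariableSchema("wt", "ct_outcome", "continuous"),
)

ANALYSIS_COLUMNS = tuple(v.name for v in COHORT_SCHEMA)
BINARY_COLUMNS = tuple(v.name for v in COHORT_SCHEMA if v.scale == "binary")


@dataclass
class Cohort:
    """A validated participants x variables table.

    ``data`` keeps the analysis columns (plus any appended derived columns);
    row order is meaningful and preserved by I/O. The complete-case contract
    holds: missing values among analysis variables are an input error.
    """

    data: pd.DataFrame
    provenance: str = "file"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        validate_cohort(self.data)

    @property
    def n(self) -> int:
        return len(self.data)

    def with_data(self, data: pd.DataFrame) -> "Cohort":
        return replace(self, data=data)


def _fail(msg: str) -> None:
    raise SchemaError(msg)


def validate_cohort(df: pd.DataFrame) -> None:
    """Check the schema invariants, naming the first offending row/column.

    Rows are reported 1-based over data rows (header excluded).
    """
    for col in ANALYSIS_COLUMNS:
        if col not in df.columns:
            _fail(f"missing column {col!r}")
    sub = df[list(ANALYSIS_COLUMNS)]
    for col in ANALYSIS_COLUMNS:
        vals = pd.to_numeric(sub[col], errors="coerce")
        bad = vals.isna() & sub[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            _fail(f"non-numeric value in column {col!r}, row {row}")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0]) + 1
            _fail(f"missing value in column {col!r}, row {row}")

    def first_bad(mask: pd.Series, col: str, what: str) -> None:
        if mask.any():
            row = int(np.flatnonzero(mask.to_numpy())[0]) + 1
            _fail(f"{what} in column {col!r}, row {row}")

    for col in BINARY_COLUMNS:
        first_bad(~sub[col].isin([0, 1]), col, "value outside {0,1}")
    first_bad(~sub["severity"].isin(SEVERITY_LEVELS), "severity", "severity outside {0,1,2,3}")
    first_bad(sub["tac"] < 1, "tac", "TAC below 1")
    first_bad(sub["tac_p"] < 0, "tac_p", "negative TAC_p")
    first_bad(sub["wt"] <= 0, "wt", "non-positive wall thickness")
    first_bad(sub["tac_p"] > sub["tac"], "tac_p", "TAC_p exceeds TAC")


def read_cohort(path, provenance: str = "file") -> Cohort:
    """Read and validate a cohort CSV (header row mandatory)."""
    df = pd.read_csv(path, float_precision="round_trip")
    cohort = Cohort(df, provenance=provenance)
    return cohort


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort as CSV. Floats use shortest-repr formatting, so a
    read/write cycle is value-exact and a write∘read∘write cycle is
    byte-stable."""
    cohort.data.to_csv(path, index=False)


def apply_log_transforms(cohort: Cohort) -> Cohort:
    """Append natural-log columns for TAC, TACp, WT and lung size.

    Originals are retained. Re-application is refused (idempotence contract)
    and non-positive source values are a domain error.
    """
    df = cohort.data
    present = [c for c in LOG_COLUMNS.values() if c in df.columns]
    if present:
        _fail(f"log columns already present: {present}; refusing to re-apply")
    out = df.copy()
    for src, dst in LOG_COLUMNS.items():
        vals = out[src].to_numpy(dtype=float)
        if np.any(vals <= 0):
            row = int(np.flatnonzero(vals <= 0)[0]) + 1
            _fail(f"non-positive value in column {src!r}, row {row}: cannot log-transform")
        out[dst] = np.log(vals)
    return cohort.with_data(out)


def encode_severity(cohort: Cohort, mode: str = "dummies") -> Cohort:
    """Encode COPD severity.

    ``ordinal`` leaves the 0-3 column as is; ``dummies`` appends three
    indicators (mild, moderate, severe) against the preserved reference.
    """
    if mode == "ordinal":
        return cohort
    if mode != "dummies":
        _fail(f"unknown severity encoding mode {mode!r}")
    df = cohort.data.copy()
    sev = df["severity"].to_numpy()
    for level, col in zip((1, 2, 3), SEVERITY_DUMMIES):
        df[col] = (sev == level).astype(int)
    return cohort.with_data(df)


def severity_from_dummies(df: pd.DataFrame) -> np.ndarray:
    """Reconstruct the ordinal severity code from the three dummy columns."""
    out = np.zeros(len(df), dtype=int)
    for level, col in zip((1, 2, 3), SEVERITY_DUMMIES):
        out = out + level * df[col].to_numpy(dtype=int)
    return out
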