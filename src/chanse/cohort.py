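"""Patient-level data model: CSV schema, validation, and feature derivation.

One row per patient; demographics, symptoms, physical-exam findings
(including the heel drop test), laboratory values, and the adjudicated
outcome (``none`` / ``uncomplicated`` / ``complicated`` appendicitis;
"diseased" means outcome != none).

Missing cells are permitted (nullable columns) and handled downstream by
complete-case analysis per variable: a record missing a field is excluded
only from computations that need that field.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import Thresholds, DEFAULT_THRESHOLDS

SCHEMA_VERSION = "1"

OUTCOMES = ("none", "uncomplicated", "complicated")

# column name -> kind ("str", "real", "bool", "sex", "outcome")
SCHEMA: dict[str, str] = {
    "patient_id": "str",
    "age_years": "real",
    "sex": "sex",
    "body_temp_c": "real",
    "pain_duration_h": "real",
    "anorexia": "bool",
    "nausea_or_vomiting": "bool",
    "diarrhea": "bool",
    "migration": "bool",
    "wbc_per_ul": "real",
    "neutrophil_pct": "real",
    "crp_mg_dl": "real",
    "rlq_tenderness": "bool",
    "cough_percussion_hopping": "bool",
    "psoas": "bool",
    "obturator": "bool",
    "rovsing": "bool",
    "heel_drop": "bool",
    "outcome": "outcome",
}

BOOL_COLUMNS = tuple(c for c, k in SCHEMA.items() if k == "bool")
REAL_COLUMNS = tuple(c for c, k in SCHEMA.items() if k == "real")

_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}

# derived flag -> (lab column, inclusive threshold attribute)
DERIVED_FLAGS = {
    "leukocytosis": ("wbc_per_ul", "wbc_per_ul"),
    "left_shift": ("neutrophil_pct", "neutrophil_pct"),
    "crp_elevated_1": ("crp_mg_dl", "crp_mg_dl_low"),
    "crp_elevated_5": ("crp_mg_dl", "crp_mg_dl_high"),
    "fever": ("body_temp_c", "body_temp_c"),
}

PASSTHROUGH_FLAGS = (
    "anorexia",
    "nausea_or_vomiting",
    "migration",
    "rlq_tenderness",
    "cough_percussion_hopping",
    "heel_drop",
    "psoas",
    "obturator",
    "rovsing",
    "diarrhea",
)

FEATURE_COLUMNS = tuple(DERIVED_FLAGS) + PASSTHROUGH_FLAGS


class SchemaError(ValueError):
    """Header or cell does not conform to the cohort CSV schema."""


class CohortValidationError(ValueError):
    """Parsed values violate a domain invariant (range, duplicate id, ...)."""


@dataclass
class PatientRecord:
    patient_id: str
    age_years: Optional[float]
    sex: Optional[str]
    body_temp_c: Optional[float]
    pain_duration_h: Optional[float]
    anorexia: Optional[bool]
    nausea_or_vomiting: Optional[bool]
    diarrhea: Optional[bool]
    migration: Optional[bool]
    wbc_per_ul: Optional[float]
    neutrophil_pct: Optional[float]
    crp_mg_dl: Optional[float]
    rlq_tenderness: Optional[bool]
    cough_percussion_hopping: Optional[bool]
    psoas: Optional[bool]
    obturator: Optional[bool]
    rovsing: Optional[bool]
    heel_drop: Optional[bool]
    outcome: str

    @property
    def diseased(self) -> bool:
        return self.outcome != "none"


class Cohort:
    """Ordered collection of patient records, backed by a pandas DataFrame.

    ``df`` carries one column per :data:`SCHEMA` entry with nullable dtypes
    (``boolean`` for flags, ``float64`` for reals).  ``provenance`` is free
    text (a source path or a generator seed description).
    """

    def __init__(self, df: pd.DataFrame, provenance: str = "") -> None:
        self.df = df.reset_index(drop=True)
        self.provenance = provenance
        self.validate()

    def __len__(self) -> int:
        return len(self.df)

    def validate(self) -> None:
        df = self.df
        missing = [c for c in SCHEMA if c not in df.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        if len(df) == 0:
            raise CohortValidationError("cohort is empty")
        dup = df["patient_id"][df["patient_id"].duplicated()]
        if len(dup):
            raise CohortValidationError(
                f"duplicate patient_id values: {sorted(set(dup))}"
            )
        bad_outcome = ~df["outcome"].isin(OUTCOMES)
        if bad_outcome.any():
            row = int(np.flatnonzero(bad_outcome)[0])
            raise CohortValidationError(
                f"row {row}: outcome {df['outcome'].iloc[row]!r} not in {OUTCOMES}"
            )
        sex_ok = df["sex"].isna() | df["sex"].isin(["male", "female"])
        if not sex_ok.all():
            row = int(np.flatnonzero(~sex_ok)[0])
            raise CohortValidationError(f"row {row}: sex must be male/female")
        for col, lo, hi in [
            ("neutrophil_pct", 0.0, 100.0),
            ("wbc_per_ul", 0.0, np.inf),
            ("crp_mg_dl", 0.0, np.inf),
            ("age_years", 0.0, np.inf),
            ("pain_duration_h", 0.0, np.inf),
        ]:
            vals = df[col]
            bad = vals.notna() & ((vals < lo) | (vals > hi))
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise CohortValidationError(
                    f"row {row}: {col}={vals.iloc[row]} outside [{lo}, {hi}]"
                )

    @property
    def diseased(self) -> pd.Series:
        return self.df["outcome"] != "none"

    def to_records(self) -> list[PatientRecord]:
        out = []
        names = [f.name for f in dc_fields(PatientRecord)]
        for _, row in self.df.iterrows():
            kw = {}
            for name in names:
                v = row[name]
                kw[name] = None if pd.isna(v) else v
            out.append(PatientRecord(**kw))
        return out


def _parse_bool_series(raw: pd.Series, col: str) -> pd.Series:
    s = raw.astype("string").str.strip().str.lower()
    out = pd.Series(pd.NA, index=raw.index, dtype="boolean")
    out[s.isin(_TRUE)] = True
    out[s.isin(_FALSE)] = False
    bad = s.notna() & (s != "") & ~s.isin(_TRUE | _FALSE)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise SchemaError(
            f"row {row}, column {col!r}: cannot parse boolean {raw.iloc[row]!r}"
        )
    return out


def _parse_real_series(raw: pd.Series, col: str) -> pd.Series:
    s = raw.astype("string").str.strip()
    s = s.mask(s == "", pd.NA)
    out = np.full(len(s), np.nan)
    # float() is correctly rounded (unlike pandas' fast csv float path),
    # keeping the CSV round-trip bit-exact
    for i, v in enumerate(s):
        if v is pd.NA:
            continue
        try:
            out[i] = float(v)
        except ValueError:
            raise SchemaError(
                f"row {i}, column {col!r}: cannot parse number {raw.iloc[i]!r}"
            ) from None
    return pd.Series(out, index=raw.index)


def read_cohort(path: str | Path | io.TextIOBase, schema_version: str = SCHEMA_VERSION) -> Cohort:
    """Read and validate a cohort CSV (RFC-4180, UTF-8, header required).

    Header matching is case-insensitive; booleans accept 0/1, true/false,
    yes/no; empty cells become missing values.
    """
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {schema_version!r}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    raw.columns = [c.strip().lower() for c in raw.columns]
    unknown = [c for c in raw.columns if c not in SCHEMA]
    if unknown:
        raise SchemaError(f"unknown columns: {unknown}")
    missing = [c for c in SCHEMA if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")

    df = pd.DataFrame(index=raw.index)
    for col, kind in SCHEMA.items():
        if kind == "bool":
            df[col] = _parse_bool_series(raw[col], col)
        elif kind == "real":
            df[col] = _parse_real_series(raw[col], col)
        elif kind == "sex":
            s = raw[col].str.strip().str.lower()
            df[col] = s.mask(s == "", pd.NA).astype("string")
        elif kind == "outcome":
            df[col] = raw[col].str.strip().str.lower()
        else:
            df[col] = raw[col].str.strip()
    provenance = str(path) if isinstance(path, (str, Path)) else "<stream>"
    return Cohort(df, provenance=provenance)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort CSV: fixed column order, booleans as 0/1, reals unrounded."""
    df = cohort.df[list(SCHEMA)].copy()
    for col in BOOL_COLUMNS:
        df[col] = df[col].astype("Int8")
    df.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")


def derive_features(
    cohort: Cohort | pd.DataFrame, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Derive the binary feature table feeding the scores.

    Lab flags are inclusive threshold comparisons (``>=``); symptom and exam
    flags pass through.  A missing lab value yields a missing flag, which
    downstream scoring propagates (complete-case per variable).
    """
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    feats = pd.DataFrame(index=df.index)
    for flag, (lab, attr) in DERIVED_FLAGS.items():
        thr = getattr(thresholds, attr)
        vals = df[lab]
        out = pd.Series(pd.NA, index=df.index, dtype="boolean")
        ok = vals.notna()
        out[ok] = vals[ok] >= thr
        feats[flag] = out
    for flag in PASSTHROUGH_FLAGS:
        feats[flag] = df[flag].astype("boolean")
    return feats
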