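"""Claims-shaped input tables: schemas, validation, readers and writers.

Three comma-delimited UTF-8 tables with mandatory header rows describe a study
extract:

``persons.csv``
    ``person_id, birth_year, sex, plan`` — one row per enrollee. ``sex`` is
    ``F``/``M``; ``plan`` is ``medicare``/``commercial``. Birth dates are kept
    at year resolution, which is what de-identified claims extracts carry.

``claims.csv``
    ``person_id, service_date, icd9, claim_kind`` — one row per service line
    carrying a diagnosis. ``service_date`` is ISO-8601; ``icd9`` is normalized
    on read (see :mod:`comoscreen.icd9`); ``claim_kind`` distinguishes
    encounter claims from lab / radiology / pharmacy lines, because cohort
    definitions count only non-diagnostic-service (encounter) claims.

``enrollment.csv``
    ``person_id, start, end`` — enrollment spells; spells for one person may
    not overlap and must satisfy ``start <= end``.

Readers return plain :class:`pandas.DataFrame` objects with parsed dtypes; all
invariants are enforced on read and every violation is reported with its row
number so rejects can be audited.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import SchemaError
from .icd9 import normalize_icd9

__all__ = [
    "PERSON_COLUMNS",
    "CLAIM_COLUMNS",
    "ENROLLMENT_COLUMNS",
    "SEXES",
    "PLANS",
    "CLAIM_KINDS",
    "read_persons",
    "read_claims",
    "read_enrollment",
    "write_persons",
    "write_claims",
    "write_enrollment",
    "validate_persons",
    "validate_claims",
    "validate_enrollment",
]

PERSON_COLUMNS = ["person_id", "birth_year", "sex", "plan"]
CLAIM_COLUMNS = ["person_id", "service_date", "icd9", "claim_kind"]
ENROLLMENT_COLUMNS = ["person_id", "start", "end"]

SEXES = frozenset({"F", "M"})
PLANS = frozenset({"medicare", "commercial"})
CLAIM_KINDS = frozenset({"encounter", "lab", "radiology", "pharmacy"})


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}; found {list(df.columns)}")


def _bad_rows(mask: pd.Series, df: pd.DataFrame, what: str, detail: str) -> None:
    """Raise naming offending rows (0-based data row numbers) and values."""
    if mask.any():
        idx = df.index[mask][:10].tolist()
        sample = df.loc[df.index[mask][:5]].to_dict("records")
        raise SchemaError(f"{what}: {detail} in row(s) {idx}: {sample}")


def _parse_dates(df: pd.DataFrame, col: str, what: str) -> pd.Series:
    if pd.api.types.is_datetime64_any_dtype(df[col]):
        parsed = df[col]
    else:
        parsed = pd.to_datetime(df[col], format="ISO8601", errors="coerce")
    _bad_rows(parsed.isna() & df[col].notna(), df, what, f"unparseable date in {col!r}")
    _bad_rows(parsed.isna(), df, what, f"missing date in {col!r}")
    return parsed


def validate_persons(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and coerce a persons table; returns a copy with clean dtypes."""
    _require_columns(df, PERSON_COLUMNS, "persons")
    df = df.loc[:, PERSON_COLUMNS].copy()
    df["person_id"] = df["person_id"].astype(str)
    dup = df["person_id"].duplicated(keep=False)
    _bad_rows(dup, df, "persons", "duplicate person_id")
    birth = pd.to_numeric(df["birth_year"], errors="coerce")
    _bad_rows(birth.isna() | (birth != birth.round()), df, "persons", "non-integer birth_year")
    df["birth_year"] = birth.astype(int)
    _bad_rows(~df["sex"].isin(SEXES), df, "persons", f"sex not in {sorted(SEXES)}")
    _bad_rows(~df["plan"].isin(PLANS), df, "persons", f"plan not in {sorted(PLANS)}")
    return df.reset_index(drop=True)


def validate_claims(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and coerce a claims table; ICD-9 codes are normalized."""
    _require_columns(df, CLAIM_COLUMNS, "claims")
    df = df.loc[:, CLAIM_COLUMNS].copy()
    df["person_id"] = df["person_id"].astype(str)
    df["service_date"] = _parse_dates(df, "service_date", "claims")
    _bad_rows(~df["claim_kind"].isin(CLAIM_KINDS), df, "claims",
              f"claim_kind not in {sorted(CLAIM_KINDS)}")
    raw = df["icd9"].astype(str)
    normalized = np.empty(len(df), dtype=object)
    bad: list[int] = []
    for i, (row, value) in enumerate(zip(df.index, raw)):
        try:
            normalized[i] = normalize_icd9(value)
        except Exception:
            bad.append(row)
    if bad:
        values = raw.loc[bad[:5]].tolist()
        raise SchemaError(f"claims: malformed icd9 in row(s) {bad[:10]}: {values}")
    df["icd9"] = normalized
    return df.reset_index(drop=True)


def validate_enrollment(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an enrollment-spell table: start <= end, no overlap per person."""
    _require_columns(df, ENROLLMENT_COLUMNS, "enrollment")
    df = df.loc[:, ENROLLMENT_COLUMNS].copy()
    df["person_id"] = df["person_id"].astype(str)
    df["start"] = _parse_dates(df, "start", "enrollment")
    df["end"] = _parse_dates(df, "end", "enrollment")
    _bad_rows(df["start"] > df["end"], df, "enrollment", "spell start after end")
    ordered = df.sort_values(["person_id", "start"])
    same_person = ordered["person_id"].eq(ordered["person_id"].shift())
    overlaps = same_person & (ordered["start"] <= ordered["end"].shift())
    if overlaps.any():
        rows = ordered.index[overlaps][:10].tolist()
        raise SchemaError(f"enrollment: overlapping spells for one person in row(s) {rows}")
    return df.reset_index(drop=True)


def _read(path: "str | Path", what: str) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path, dtype={"person_id": str})
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{what}: {path} has no header row") from None


def read_persons(path: "str | Path") -> pd.DataFrame:
    return validate_persons(_read(path, "persons"))


def read_claims(path: "str | Path") -> pd.DataFrame:
    return validate_claims(_read(path, "claims"))


def read_enrollment(path: "str | Path") -> pd.DataFrame:
    return validate_enrollment(_read(path, "enrollment"))


def _iso(series: pd.Series) -> pd.Series:
    return pd.to_datetime(series).dt.strftime("%Y-%m-%d")


def write_persons(df: pd.DataFrame, path: "str | Path") -> None:
    df.loc[:, PERSON_COLUMNS].to_csv(path, index=False)


def write_claims(df: pd.DataFrame, path: "str | Path") -> None:
    out = df.loc[:, CLAIM_COLUMNS].copy()
    out["service_date"] = _iso(out["service_date"])
    out.to_csv(path, index=False)


def write_enrollment(df: pd.DataFrame, path: "str | Path") -> None:
    out = df.loc[:, ENROLLMENT_COLUMNS].copy()
    out["start"] = _iso(out["start"])
    out["end"] = _iso(out["end"])
    out.to_csv(path, index=False)


def as_timestamp(d: "dt.date | str | pd.Timestamp") -> pd.Timestamp:
    """Coerce a date-like value to a pandas Timestamp (midnight)."""
    return pd.Timestamp(d)
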