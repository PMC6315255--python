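"""Plain-CSV input/output for epoch traces, covariates, capacity measures
and derived artifacts.

Epoch files are long-format CSV with columns ``subject_id, timestamp,
count``: one row per recorded minute, timestamps ISO-8601 to the minute.
A subject-day is the calendar date of the timestamp; no timezone
arithmetic is performed.  Missing minutes inside a day are gaps, not
zeros — absence of a record means "no record", a zero count means "no
movement".
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Closed vocabulary for the osteoarthritis subcohort label.
OA_SUBCOHORTS = ("control", "incidence", "progression")
SEX_LEVELS = ("F", "M")

CAPACITY_COLUMNS = ("walk400_time", "walk20_pace", "sitstand_rate")


class FormatError(ValueError):
    """A required column is missing or the file cannot be parsed."""


class ValidationError(ValueError):
    """A parsed value violates a domain invariant."""


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def read_epochs(path: str | os.PathLike) -> pd.DataFrame:
    """Read a minute-epoch activity file.

    Returns a DataFrame with columns ``subject_id`` (str), ``timestamp``
    (datetime64, minute resolution), ``day`` (date) and ``count`` (int),
    sorted by subject then time.  Duplicate (subject, timestamp) pairs,
    negative or non-integer counts are rejected.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    _require_columns(df, ["subject_id", "timestamp", "count"], path)
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna())[0])
        raise ValidationError(f"{path}: unparseable timestamp at row {row}")
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna() | (counts != counts.round()) | (counts < 0)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"{path}: count must be a nonnegative integer (row {row}, "
            f"value {df['count'].iloc[row]!r})"
        )
    out = pd.DataFrame(
        {
            "subject_id": df["subject_id"].astype(str),
            "timestamp": ts.dt.floor("min"),
            "count": counts.astype(np.int64),
        }
    )
    if out.duplicated(["subject_id", "timestamp"]).any():
        dup = out[out.duplicated(["subject_id", "timestamp"])].iloc[0]
        raise ValidationError(
            f"{path}: duplicate record for subject {dup.subject_id!r} "
            f"at {dup.timestamp}"
        )
    out = out.sort_values(["subject_id", "timestamp"], kind="stable")
    out["day"] = out["timestamp"].dt.normalize()
    return out.reset_index(drop=True)[["subject_id", "timestamp", "day", "count"]]


def read_covariates(path: str | os.PathLike) -> pd.DataFrame:
    """Read subject covariates (BMI, age, sex, height, OA subcohort)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    _require_columns(
        df, ["subject_id", "bmi", "age", "sex", "height", "oa_subcohort"], path
    )
    if df.empty:
        logger.warning("%s: empty covariate file", path)
        return df
    for col in ("bmi", "age", "height"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals <= 0).any():
            raise ValidationError(f"{path}: {col} must be strictly positive")
        df[col] = vals.astype(float)
    sex = df["sex"].astype(str).str.upper().str[0]
    if not sex.isin(SEX_LEVELS).all():
        raise ValidationError(f"{path}: sex must be one of {SEX_LEVELS}")
    df["sex"] = pd.Categorical(sex, categories=SEX_LEVELS)
    sub = df["oa_subcohort"].astype(str).str.lower()
    if not sub.isin(OA_SUBCOHORTS).all():
        bad = sub[~sub.isin(OA_SUBCOHORTS)].iloc[0]
        raise ValidationError(
            f"{path}: unknown oa_subcohort label {bad!r}; "
            f"expected one of {OA_SUBCOHORTS}"
        )
    df["oa_subcohort"] = pd.Categorical(sub, categories=OA_SUBCOHORTS)
    return df.sort_values("subject_id", kind="stable").reset_index(drop=True)


def read_capacity(path: str | os.PathLike) -> pd.DataFrame:
    """Read physical-capacity measures; empty cells denote missing tests."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    _require_columns(df, ["subject_id", *CAPACITY_COLUMNS], path)
    for col in CAPACITY_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        present_bad = vals.notna() & (vals <= 0)
        if present_bad.any():
            raise ValidationError(f"{path}: {col} must be strictly positive")
        df[col] = vals.astype(float)
    return df.sort_values("subject_id", kind="stable").reset_index(drop=True)


def write_table(
    records: pd.DataFrame, path: str | os.PathLike, allow_empty: bool = False
) -> None:
    """Write any derived tabular artifact as CSV.

    Floats are written at full repr precision so read(write(x)) == x.
    An empty frame is only written when ``allow_empty`` is set (a
    header-only file results).
    """
    if records.empty and not allow_empty:
        raise ValidationError(f"refusing to write empty table to {path}")
    records.to_csv(path, index=False)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Counterpart to :func:`write_table` for round-tripping artifacts."""
    return pd.read_csv(path, dtype={"subject_id": str})
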