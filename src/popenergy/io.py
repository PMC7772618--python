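"""Input validation and CSV readers/writers for the pipeline formats.

All files are UTF-8 comma-separated with a mandatory header row,
ISO-8601 dates and empty fields for missing values.
"""

from __future__ import annotations

import datetime as _dt
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import CaptureRecord

logger = logging.getLogger(__name__)

__all__ = ["SchemaError", "read_captures", "read_ice", "read_abundance",
           "read_climate", "validate_inputs"]


class SchemaError(ValueError):
    """A table failed validation; the message names file, row and column."""

    def __init__(self, file: str, message: str, row: int | None = None,
                 column: str | None = None):
        loc = f"{file}"
        if column is not None:
            loc += f", column {column!r}"
        if row is not None:
            loc += f", row {row}"
        super().__init__(f"{loc}: {message}")
        self.file, self.row, self.column = file, row, column


def _require_columns(df: pd.DataFrame, cols: list[str], fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(fname, f"missing required column(s) {missing}",
                          column=missing[0])


def _check_range(df: pd.DataFrame, col: str, lo: float, hi: float,
                 fname: str, allow_nan: bool = False) -> None:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad_parse = vals.isna() & df[col].notna() & (df[col].astype(str) != "")
    if not allow_nan and vals.isna().any():
        idx = int(vals.index[vals.isna()][0])
        raise SchemaError(fname, "missing or non-numeric value",
                          row=idx, column=col)
    if bad_parse.any():
        idx = int(bad_parse.index[bad_parse][0])
        raise SchemaError(fname, f"non-numeric value {df[col][idx]!r}",
                          row=idx, column=col)
    out = (vals < lo) | (vals > hi)
    if out.any():
        idx = int(out.index[out][0])
        raise SchemaError(fname, f"value {vals[idx]} outside [{lo}, {hi}]",
                          row=idx, column=col)


def read_captures(path) -> list[CaptureRecord]:
    """Read and validate captures.csv into CaptureRecord objects."""
    fname = str(path)
    df = pd.read_csv(path)
    _require_columns(df, ["bear_id", "date", "sex", "age_years",
                          "with_offspring", "length_cm", "girth_cm"], fname)
    _check_range(df, "age_years", 0, 45, fname)
    _check_range(df, "length_cm", 1, 400, fname, allow_nan=True)
    _check_range(df, "girth_cm", 1, 400, fname, allow_nan=True)
    records = []
    for i, r in df.iterrows():
        try:
            date = _dt.date.fromisoformat(str(r["date"]))
        except ValueError as exc:
            raise SchemaError(fname, f"bad ISO-8601 date {r['date']!r}",
                              row=int(i), column="date") from exc
        sex = None if pd.isna(r["sex"]) else str(r["sex"]).upper()
        length = None if pd.isna(r["length_cm"]) else float(r["length_cm"])
        girth = None if pd.isna(r["girth_cm"]) else float(r["girth_cm"])
        records.append(CaptureRecord(
            bear_id=str(r["bear_id"]), date=date, sex=sex,
            age_years=int(r["age_years"]),
            with_offspring=bool(r["with_offspring"]),
            length_cm=length, girth_cm=girth))
    return records


def read_ice(path) -> pd.DataFrame:
    """Read and validate ice_daily.csv (region-mean or per-cell long form)."""
    fname = str(path)
    df = pd.read_csv(path)
    _require_columns(df, ["year", "doy", "concentration_pct"], fname)
    _check_range(df, "doy", 1, 366, fname)
    _check_range(df, "concentration_pct", 0, 100, fname, allow_nan=True)
    return df


def read_abundance(path) -> pd.DataFrame:
    fname = str(path)
    df = pd.read_csv(path)
    _require_columns(df, ["year", "n_mean", "n_se"], fname)
    _check_range(df, "n_mean", 1e-9, 1e9, fname)
    _check_range(df, "n_se", 0, 1e9, fname)
    return df


def read_climate(path) -> pd.DataFrame:
    fname = str(path)
    df = pd.read_csv(path)
    _require_columns(df, ["year", "month", "ao", "nao"], fname)
    _check_range(df, "month", 1, 12, fname)
    return df


def validate_inputs(captures_path=None, ice_path=None, abundance_path=None,
                    climate_path=None) -> dict:
    """Validate whichever input files are given; return the parsed tables.

    Raises :class:`SchemaError` naming file, row and column on the first
    failure.
    """
    out = {}
    if captures_path is not None:
        out["captures"] = read_captures(captures_path)
        logger.info("captures: %d records", len(out["captures"]))
    if ice_path is not None:
        out["ice"] = read_ice(ice_path)
        logger.info("ice: %d daily rows", len(out["ice"]))
    if abundance_path is not None:
        out["abundance"] = read_abundance(abundance_path)
        logger.info("abundance: %d years", len(out["abundance"]))
    if climate_path is not None:
        out["climate"] = read_climate(climate_path)
        logger.info("climate: %d monthly rows", len(out["climate"]))
    return out
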