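"""Sea-ice phenology and winter climate covariates.

Breakup is the first spring ordinal date on which the region-mean ice
concentration is <= 50% for three consecutive days; freeze-up the first
autumn date with >= 10% for three consecutive days.  The open-water
(on-land fasting) period is freeze-up - breakup - 25 days, the offset
accounting for bears coming ashore roughly 3-4 weeks after breakup.
Winter climate is summarized as AOw (mean Jan-Mar Arctic Oscillation)
and NAOw (mean Dec-Mar North Atlantic Oscillation, December attributed
to the preceding calendar year).  One-year-lagged copies of every
covariate carry the previous year's conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "NoEventFound",
    "MissingMonths",
    "IcePhenology",
    "detect_breakup",
    "detect_freezeup",
    "open_water_length",
    "winter_index",
    "annual_phenology",
    "build_covariates",
    "BREAKUP_THRESHOLD",
    "FREEZEUP_THRESHOLD",
    "RUN_DAYS",
    "ONSHORE_OFFSET_DAYS",
]

BREAKUP_THRESHOLD = 50.0   # % concentration, <= for breakup
FREEZEUP_THRESHOLD = 10.0  # % concentration, >= for freeze-up
RUN_DAYS = 3               # consecutive days required
ONSHORE_OFFSET_DAYS = 25   # days subtracted from freeze - break
# Default search bounds: spring search starts DOY 60, autumn search no
# earlier than DOY 213 (prevents mid-winter noise from triggering events).
BREAKUP_SEARCH_START = 60
FREEZEUP_SEARCH_START = 213


class NoEventFound(ValueError):
    """No qualifying threshold run exists in the search window."""


class MissingMonths(ValueError):
    """A winter index cannot be formed because required months are absent."""


@dataclass(frozen=True)
class IcePhenology:
    """Per-year phenology metrics (lag columns live in the covariate table)."""

    year: int
    breakup_doy: int
    freezeup_doy: int
    open_water_days: int


def _first_run(doy: np.ndarray, conc: np.ndarray, ok: np.ndarray,
               run_days: int) -> int | None:
    """First doy starting a run of `run_days` consecutive present days all `ok`.

    Consecutive means doy increments of exactly 1; a missing day (gap in
    doy or NaN concentration) terminates a run.
    """
    n = len(doy)
    run = 0
    start = None
    for i in range(n):
        contiguous = i > 0 and doy[i] == doy[i - 1] + 1
        if ok[i]:
            if run > 0 and contiguous:
                run += 1
            else:
                run = 1
                start = doy[i]
        else:
            run = 0
            start = None
        if run >= run_days:
            return int(start)
    return None


def _prepare(series: pd.DataFrame, window: tuple[int, int],
             label: str) -> tuple[np.ndarray, np.ndarray]:
    df = series.sort_values("doy")
    lo, hi = window
    df = df[(df["doy"] >= lo) & (df["doy"] <= hi)]
    doy = df["doy"].to_numpy(dtype=int)
    conc = df["concentration_pct"].to_numpy(dtype=float)
    present = np.isfinite(conc)
    span = hi - lo + 1
    n_missing = span - int(present.sum())
    if span > 0 and n_missing / span >= 0.20:
        logger.warning("%s window [%d, %d]: %d/%d days missing",
                       label, lo, hi, n_missing, span)
    if int(present.sum()) < RUN_DAYS:
        raise NoEventFound(f"fewer than {RUN_DAYS} days of data in {label} window")
    return doy[present], conc[present]


def detect_breakup(series: pd.DataFrame,
                   window: tuple[int, int] = (BREAKUP_SEARCH_START, 365),
                   threshold: float = BREAKUP_THRESHOLD,
                   run_days: int = RUN_DAYS) -> int:
    """First spring ordinal date with concentration <= threshold for
    `run_days` consecutive days.  Returns the first day of the run.

    `series` is a one-year DataFrame with columns doy, concentration_pct.
    """
    doy, conc = _prepare(series, window, "breakup")
    d = _first_run(doy, conc, conc <= threshold, run_days)
    if d is None:
        raise NoEventFound(
            f"no {run_days}-day run <= {threshold}% in window {window}")
    return d


def detect_freezeup(series: pd.DataFrame,
                    window: tuple[int, int] = (FREEZEUP_SEARCH_START, 365),
                    threshold: float = FREEZEUP_THRESHOLD,
                    run_days: int = RUN_DAYS) -> int:
    """First autumn ordinal date with concentration >= threshold for
    `run_days` consecutive days.  The window should begin after breakup."""
    doy, conc = _prepare(series, window, "freezeup")
    d = _first_run(doy, conc, conc >= threshold, run_days)
    if d is None:
        raise NoEventFound(
            f"no {run_days}-day run >= {threshold}% in window {window}")
    return d


def open_water_length(breakup_doy: int, freezeup_doy: int,
                      onshore_offset: int = ONSHORE_OFFSET_DAYS) -> int:
    """On-land fasting period: freeze-up - breakup - onshore offset (days)."""
    if freezeup_doy <= breakup_doy:
        raise ValueError(
            f"freeze-up ({freezeup_doy}) must be after breakup ({breakup_doy})")
    return int(freezeup_doy) - int(breakup_doy) - int(onshore_offset)


def annual_phenology(ice: pd.DataFrame,
                     breakup_threshold: float = BREAKUP_THRESHOLD,
                     freezeup_threshold: float = FREEZEUP_THRESHOLD,
                     run_days: int = RUN_DAYS,
                     onshore_offset: int = ONSHORE_OFFSET_DAYS,
                     breakup_search_start: int = BREAKUP_SEARCH_START,
                     freezeup_search_start: int = FREEZEUP_SEARCH_START,
                     ) -> pd.DataFrame:
    """Detect breakup/freeze-up per year of a daily concentration table.

    `ice` has columns year, doy, concentration_pct (region means), or a
    per-cell long format with an extra cell_id column — per-cell values
    are averaged per day before thresholding.  Years where either event
    is undetectable are skipped with a warning.
    """
    if "cell_id" in ice.columns:
        ice = (ice.groupby(["year", "doy"], as_index=False)["concentration_pct"]
               .mean())
    rows = []
    for year, grp in ice.groupby("year"):
        try:
            b = detect_breakup(grp, (breakup_search_start, 365),
                               breakup_threshold, run_days)
            f = detect_freezeup(grp, (max(b + run_days, freezeup_search_start), 366),
                                freezeup_threshold, run_days)
            rows.append(IcePhenology(int(year), b, f,
                                     open_water_length(b, f, onshore_offset)))
        except NoEventFound as exc:
            logger.warning("year %s: %s", year, exc)
    return pd.DataFrame(
        [{"year": p.year, "breakup_doy": p.breakup_doy,
          "freezeup_doy": p.freezeup_doy, "open_water_days": p.open_water_days}
         for p in rows]
    )


def winter_index(monthly: pd.DataFrame, scheme: str, value_col: str) -> pd.Series:
    """Winter mean of a monthly climate index.

    scheme "AO": mean of January-March of year y.
    scheme "NAO": mean of December of y-1 through March of y (December is
    attributed to the winter it opens).  Years whose required months are
    entirely absent raise MissingMonths; a year missing only the prior
    December (series start) gets NaN.
    """
    scheme = scheme.upper()
    if scheme not in ("AO", "NAO"):
        raise ValueError(f"unknown scheme {scheme!r}")
    df = monthly[["year", "month", value_col]].dropna()
    pivot = df.pivot_table(index="year", columns="month", values=value_col)
    years = sorted(pivot.index)
    out = {}
    for y in years:
        if scheme == "AO":
            months = [pivot.at[y, m] if m in pivot.columns and y in pivot.index
                      else np.nan for m in (1, 2, 3)]
            if np.all(np.isnan(months)):
                raise MissingMonths(f"no Jan-Mar values for year {y}")
            if np.any(np.isnan(months)):
                raise MissingMonths(f"missing Jan-Mar month(s) for year {y}")
            out[y] = float(np.mean(months))
        else:
            jfm = [pivot.at[y, m] if m in pivot.columns else np.nan
                   for m in (1, 2, 3)]
            dec = (pivot.at[y - 1, 12]
                   if (y - 1) in pivot.index and 12 in pivot.columns else np.nan)
            if np.any(np.isnan(jfm)):
                raise MissingMonths(f"missing Jan-Mar month(s) for year {y}")
            if np.isnan(dec):
                out[y] = np.nan  # series start: no prior December
            else:
                out[y] = float(np.mean([dec] + jfm))
    return pd.Series(out, name=f"{scheme.lower()}_winter").rename_axis("year")


def build_covariates(phenology: pd.DataFrame,
                     climate: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assemble the annual environmental covariate table with lag-1 columns.

    `phenology` is the output of :func:`annual_phenology`; `climate` (if
    given) has columns year, month, ao, nao.  Rows are sorted by year;
    the first year's lag columns are NaN.  Row count equals the phenology
    row count.
    """
    df = phenology.sort_values("year").reset_index(drop=True).copy()
    if climate is not None:
        ao = winter_index(climate, "AO", "ao")
        nao = winter_index(climate, "NAO", "nao")
        df = df.merge(ao.rename("ao_winter"), left_on="year", right_index=True,
                      how="left")
        df = df.merge(nao.rename("nao_winter"), left_on="year", right_index=True,
                      how="left")
    lag_cols = [c for c in ("breakup_doy", "freezeup_doy", "open_water_days",
                            "ao_winter", "nao_winter") if c in df.columns]
    # lag-1 only meaningful across consecutive years
    year_gap = df["year"].diff()
    for c in lag_cols:
        lagged = df[c].shift(1)
        lagged[year_gap != 1] = np.nan
        df[f"{c}_lag1"] = lagged
    return df
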