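"""Population interpolation and monthly death rates.

Annual population estimates are treated as July-1 anchors and interpolated
to the month-end dates carrying the death counts; rates are deaths per
100,000 persons per month.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def assign_month_end_dates(year_months) -> pd.DatetimeIndex:
    """Map (year, month) pairs to the final calendar day of each month.

    Monthly death counts cover the whole month, so each observation is
    anchored to its month end (leap-aware: February 2020 -> Feb 29).
    """
    stamps = [pd.Timestamp(y, m, 1) + pd.offsets.MonthEnd(0) for y, m in year_months]
    return pd.DatetimeIndex(stamps)


def interpolate_population(anchors: pd.Series, target_dates,
                           method: str = "time") -> pd.Series:
    """Interpolate annual July-1 population anchors to arbitrary dates.

    Parameters
    ----------
    anchors : Series
        Population indexed by the July-1 anchor dates (DatetimeIndex), one
        per consecutive year.
    target_dates : DatetimeIndex or sequence of dates
    method : {"time", "month"}
        "time" interpolates linearly in elapsed calendar days (so a
        July-to-July span is 365 or 366 days as the calendar dictates);
        "month" interpolates linearly in month counts, for sensitivity
        checks.

    Dates before the first anchor backfill the first anchor's value; dates
    after the last anchor carry the last anchor's value forward.
    """
    if len(anchors) == 0:
        raise ValueError("no population anchors supplied")
    anchors = anchors.sort_index()
    if (anchors <= 0).any():
        raise ValueError("population anchors must be strictly positive")
    years = anchors.index.year
    if len(years) > 1 and not np.all(np.diff(years) == 1):
        raise ValueError("anchor years must be consecutive")

    targets = pd.DatetimeIndex(target_dates)
    if method == "time":
        combined = anchors.reindex(anchors.index.union(targets))
        out = combined.interpolate(method="time").bfill().ffill()
    elif method == "month":
        def months(ix):
            return ix.year * 12 + ix.month + (ix.day - 1) / 31.0
        xa = months(anchors.index)
        xt = months(targets)
        out_vals = np.interp(xt, xa, anchors.to_numpy())
        return pd.Series(out_vals, index=targets, name="population")
    else:
        raise ValueError(f"unknown interpolation method {method!r}")
    return out.loc[targets].rename("population")


def compute_death_rate(deaths, population):
    """Monthly death rate per 100,000 persons: y = 100000 * d / p."""
    d = np.asarray(deaths, dtype=float)
    p = np.asarray(population, dtype=float)
    if np.any(p <= 0):
        raise ValueError("population must be strictly positive")
    if np.any(d < 0):
        raise ValueError("death counts must be non-negative")
    out = 100000.0 * d / p
    if out.ndim == 0:
        return float(out)
    return out


def rate_to_deaths(rate, population):
    """Inverse of :func:`compute_death_rate`: d = rate * p / 100000."""
    return np.asarray(rate, dtype=float) * np.asarray(population, dtype=float) / 100000.0


def monthly_population(pop_table: pd.DataFrame, year_months,
                       method: str = "time") -> pd.DataFrame:
    """Interpolate a stratified annual population table to monthly values.

    ``pop_table`` has columns (region, gender, year, population); the result
    has one row per stratum per month with columns (region, gender, year,
    month, date, population).
    """
    dates = assign_month_end_dates(year_months)
    frames = []
    for (region, gender), grp in pop_table.groupby(["region", "gender"], sort=True):
        anchors = pd.Series(
            grp["population"].to_numpy(dtype=float),
            index=pd.DatetimeIndex([pd.Timestamp(int(y), 7, 1) for y in grp["year"]]),
        )
        interp = interpolate_population(anchors, dates, method=method)
        frames.append(pd.DataFrame({
            "region": region, "gender": gender,
            "year": [ym[0] for ym in year_months],
            "month": [ym[1] for ym in year_months],
            "date": dates, "population": interp.to_numpy(),
        }))
    return pd.concat(frames, ignore_index=True)


def read_population_csv(path) -> pd.DataFrame:
    """Read an annual population table (region, gender, year, population)."""
    df = pd.read_csv(path)
    required = {"region", "gender", "year", "population"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"population file missing columns: {sorted(missing)}")
    return df


def write_rate_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
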