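"""No-pandemic counterfactual projection and excess death accounting.

The counterfactual death rate sets the COVID indicator, months-since-COVID
and months-since-CHW terms to zero, extrapolating the pre-pandemic fit.
Excess rate r_t = y_t - y~_t; excess deaths s_t = r_t * p_t / 100000;
cumulative excess c_t sums s from the pandemic's first month (t = 255 under
the default timeline, March 2020).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import COUNTERFACTUAL_ZEROED, REGIONS
from .fit import FitResult, predict_with_intervals

COVID_START_T = 255


def zero_pandemic_columns(X: pd.DataFrame,
                          zeroed=COUNTERFACTUAL_ZEROED) -> pd.DataFrame:
    """Copy of the design with the pandemic-era columns set to zero."""
    out = X.copy()
    for col in zeroed:
        if col in out.columns:
            out[col] = 0.0
    return out


def counterfactual_predict(fit: FitResult, X_cf: pd.DataFrame,
                           level: float = 0.95,
                           zeroed=COUNTERFACTUAL_ZEROED) -> pd.DataFrame:
    """Counterfactual rates with prediction intervals.

    ``X_cf`` must already have the pandemic columns zeroed (use
    :func:`zero_pandemic_columns`); any nonzero entry there raises, guarding
    against accidental leakage of pandemic terms into the projection.
    """
    for col in zeroed:
        if col in X_cf.columns and (X_cf[col].to_numpy() != 0).any():
            raise ValueError(f"counterfactual design has nonzero entries in {col!r}; "
                             "zero the pandemic columns first")
    return predict_with_intervals(fit, X_cf, level=level)


def excess_series(observed: pd.Series, counterfactual: pd.Series,
                  population: pd.Series, start_t: int = COVID_START_T) -> pd.DataFrame:
    """Excess rate, excess deaths and cumulative excess deaths from start_t on.

    All three inputs are indexed by month index t and must align on every
    month >= start_t. Excess quantities are kept real-valued; rounding is a
    reporting concern.
    """
    months = observed.index[observed.index >= start_t]
    for name, s in (("counterfactual", counterfactual), ("population", population)):
        missing = months.difference(s.index)
        if len(missing):
            raise ValueError(f"{name} series missing months {list(missing[:3])}")
    y = observed.loc[months].to_numpy(dtype=float)
    ycf = counterfactual.loc[months].to_numpy(dtype=float)
    p = population.loc[months].to_numpy(dtype=float)
    r = y - ycf
    s = r * p / 100000.0
    c = np.cumsum(s)
    return pd.DataFrame({"observed": y, "counterfactual": ycf,
                         "excess_rate": r, "excess_deaths": s,
                         "cumulative_excess": c},
                        index=pd.Index(months, name="t"))


def aggregate_national(per_region: dict[str, pd.Series],
                       required=REGIONS) -> pd.Series:
    """Elementwise sum of regional series (e.g. cumulative excess deaths)."""
    missing = [r for r in required if r not in per_region]
    if missing:
        raise ValueError(f"missing region(s): {missing}")
    series = [per_region[r] for r in required]
    months = series[0].index
    for r, s in zip(required, series):
        if not months.equals(s.index):
            raise ValueError(f"region {r!r} not aligned on the same months")
    total = sum(s.to_numpy(dtype=float) for s in series)
    return pd.Series(total, index=months, name="national")


def attribution_percent(oced: float, nced: float | None = None, *,
                        aced: float | None = None,
                        covid_deaths: float | None = None,
                        covid_share: float | None = None) -> float:
    """Percentage of non-COVID excess deaths attributable to opioids.

    nCED may be given directly (preferred when an externally published value
    exists), or derived as aCED - COVID-19 deaths, or as aCED * (1 - share).
    Returns 100 * oCED / nCED, unrounded.
    """
    if nced is None:
        if aced is None:
            raise ValueError("need nced, or aced with covid_deaths or covid_share")
        if covid_deaths is not None:
            nced = aced - covid_deaths
        elif covid_share is not None:
            nced = aced * (1.0 - covid_share)
        else:
            raise ValueError("need covid_deaths or covid_share alongside aced")
    if nced <= 0:
        raise ValueError(f"non-COVID excess deaths must be positive, got {nced}")
    return 100.0 * oced / nced


def attribution_table(rows: list[dict]) -> pd.DataFrame:
    """Build an attribution table from period inputs.

    Each row dict carries: period, aced, covid_share (fraction), nced
    (published value, optional), oced (model estimate). The attribution
    percentage is computed per row and reported to one decimal.
    """
    out = []
    for row in rows:
        nced = row.get("nced")
        if nced is None:
            nced = row["aced"] * (1.0 - row["covid_share"])
        pct = attribution_percent(row["oced"], nced)
        out.append({"period": row["period"], "aced": row.get("aced"),
                    "covid_share": row.get("covid_share"), "nced": nced,
                    "oced": row["oced"], "opioid_attr_pct": round(pct, 1)})
    return pd.DataFrame(out)
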