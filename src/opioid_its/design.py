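"""Intervention timeline encoding and ITS regression design matrices.

The analysis models monthly opioid-related death rates as a piecewise-linear
function of time, with predefined interventions each contributing an
*immediate* effect (a level shift, entering as a 0/1 indicator) and/or a
*sustained* effect (a slope change, entering as months elapsed since the
intervention). Months are indexed from January 1999 = 1.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

ORIGIN_YEAR = 1999

#: Census regions used for stratification.
REGIONS = ("Northeast", "Midwest", "South", "West")
GENDERS = ("Female", "Male")


def monthly_index(date) -> int:
    """Number of months since January 1999, with January 1999 = month 1.

    Accepts a ``datetime.date``/``datetime``/``pandas.Timestamp`` or a
    ``(year, month)`` tuple. The day of month is irrelevant: any date in
    March 2020 maps to index 255.
    """
    if isinstance(date, tuple):
        year, month = date
    else:
        year, month = date.year, date.month
    if year < ORIGIN_YEAR:
        raise ValueError(f"date {year}-{month:02d} precedes the January {ORIGIN_YEAR} origin")
    if not 1 <= month <= 12:
        raise ValueError(f"invalid month {month}")
    return (year - ORIGIN_YEAR) * 12 + month


def index_to_year_month(t: int) -> tuple[int, int]:
    """Inverse of :func:`monthly_index`."""
    if t < 1:
        raise ValueError(f"month index must be >= 1, got {t}")
    return ORIGIN_YEAR + (t - 1) // 12, (t - 1) % 12 + 1


@dataclass(frozen=True)
class Intervention:
    """A timeline event with its calendar date and modelled effects."""

    name: str
    date: _dt.date
    immediate: bool
    sustained: bool

    @property
    def index(self) -> int:
        return monthly_index(self.date)


@dataclass
class Timeline:
    """Ordered collection of interventions defining the ITS segments."""

    events: list[Intervention] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.date)
        names = [e.name for e in self.events]
        if len(set(names)) != len(names):
            raise ValueError("intervention names must be unique")

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def __getitem__(self, name: str) -> Intervention:
        for e in self.events:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.events]

    def column_names(self) -> list[str]:
        """Design-matrix column labels: intercept, month, then one
        ``Indicator_<name>`` per immediate effect and ``MonthsSince_<name>``
        per sustained effect, in event order."""
        cols = ["Intercept", "Month"]
        for e in self.events:
            if e.immediate:
                cols.append(f"Indicator_{e.name}")
            if e.sustained:
                cols.append(f"MonthsSince_{e.name}")
        return cols

    def to_yaml(self, path) -> None:
        data = [
            {"name": e.name, "date": e.date.isoformat(),
             "immediate": e.immediate, "sustained": e.sustained}
            for e in self.events
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Timeline":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        events = [
            Intervention(
                name=item["name"],
                date=_dt.date.fromisoformat(str(item["date"])),
                immediate=bool(item["immediate"]),
                sustained=bool(item["sustained"]),
            )
            for item in data
        ]
        return cls(events)


def default_timeline() -> Timeline:
    """The five-event opioid-epidemic timeline.

    Heroin and fentanyl waves and the COVID-19 emergency carry both an
    immediate level shift and a sustained slope change; the opioid public
    health emergency (PHE) declaration and the community-health-worker (CHW)
    funding announcement, which fall late in their months, carry sustained
    effects only. Together with the intercept and the baseline monthly
    slope this yields a 10-column design.
    """
    return Timeline([
        Intervention("Heroin", _dt.date(2010, 1, 1), immediate=True, sustained=True),
        Intervention("Fentanyl", _dt.date(2013, 1, 1), immediate=True, sustained=True),
        Intervention("PHE", _dt.date(2017, 10, 26), immediate=False, sustained=True),
        Intervention("COVID", _dt.date(2020, 3, 13), immediate=True, sustained=True),
        Intervention("CHW", _dt.date(2021, 3, 25), immediate=False, sustained=True),
    ])


#: Names of the columns zeroed when projecting the no-pandemic counterfactual.
COUNTERFACTUAL_ZEROED = ("Indicator_COVID", "MonthsSince_COVID", "MonthsSince_CHW")


def build_intervention_variables(t: int, timeline: Timeline) -> dict:
    """Indicator and elapsed-time variables for a single month.

    Returns ``I_<name>`` and ``P_<name>`` for *every* event, regardless of
    which effects enter the model: I(E) = 1{t >= index(E)} and
    P(E) = max(0, t - (index(E) - 1)), so P = 1 in the event month itself.
    """
    if t < 1:
        raise ValueError(f"month index must be >= 1, got {t}")
    row: dict = {"t": t}
    for e in timeline:
        row[f"I_{e.name}"] = int(t >= e.index)
        row[f"P_{e.name}"] = max(0, t - (e.index - 1))
    return row


def _check_contiguous(t: np.ndarray) -> None:
    if len(t) == 0:
        raise ValueError("empty month range")
    if len(t) > 1 and not np.all(np.diff(t) == 1):
        gaps = t[:-1][np.diff(t) != 1]
        raise ValueError(f"month indices are not contiguous; gap after t={int(gaps[0])}")


def build_design_matrix(t, timeline: Timeline) -> pd.DataFrame:
    """Full-model regressor matrix over a contiguous run of months.

    Parameters
    ----------
    t : sequence of int, or a DataFrame with a ``t`` column
        Month indices (January 1999 = 1); must be contiguous.
    timeline : Timeline

    Returns a DataFrame indexed by ``t`` whose columns follow
    :meth:`Timeline.column_names`: indicators for immediate effects and
    elapsed months for sustained effects, in event order.
    """
    if isinstance(t, pd.DataFrame):
        t = t["t"].to_numpy()
    t = np.asarray(t, dtype=int)
    _check_contiguous(t)
    cols: dict[str, np.ndarray] = {
        "Intercept": np.ones_like(t, dtype=float),
        "Month": t.astype(float),
    }
    for e in timeline:
        if e.immediate:
            cols[f"Indicator_{e.name}"] = (t >= e.index).astype(float)
        if e.sustained:
            cols[f"MonthsSince_{e.name}"] = np.maximum(0, t - (e.index - 1)).astype(float)
    return pd.DataFrame(cols, index=pd.Index(t, name="t"))


def build_interaction_design(stacked: pd.DataFrame, timeline: Timeline,
                             gender_col: str = "gender") -> pd.DataFrame:
    """Gender-interaction design for two stacked strata.

    ``stacked`` must hold both genders over identical months, with columns
    ``t`` and ``gender`` ("Female"/"Male"). Female is the baseline (coded 0);
    each of the base columns is duplicated, multiplied by the Male indicator,
    under a ``Male:``-prefixed name, so male coefficients are deviations from
    the female ones.
    """
    genders = set(stacked[gender_col].unique())
    if genders != set(GENDERS):
        raise ValueError(f"expected strata {set(GENDERS)}, got {genders}")
    months = {g: tuple(sorted(stacked.loc[stacked[gender_col] == g, "t"])) for g in GENDERS}
    if months["Female"] != months["Male"]:
        raise ValueError("Female and Male strata do not cover identical months")

    t = stacked["t"].to_numpy(dtype=int)
    # per-row base columns (rows need not be contiguous once stacked)
    base = pd.DataFrame(index=stacked.index)
    base["Intercept"] = 1.0
    base["Month"] = t.astype(float)
    for e in timeline:
        if e.immediate:
            base[f"Indicator_{e.name}"] = (t >= e.index).astype(float)
        if e.sustained:
            base[f"MonthsSince_{e.name}"] = np.maximum(0, t - (e.index - 1)).astype(float)
    male = (stacked[gender_col] == "Male").to_numpy().astype(float)
    inter = base.mul(male, axis=0)
    inter.columns = [f"Male:{c}" for c in base.columns]
    return pd.concat([base, inter], axis=1)
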