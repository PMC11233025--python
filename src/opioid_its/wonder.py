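"""CDC WONDER-dialect export parsing and ICD-10 opioid death filtering.

Multiple Cause of Death (MCOD) exports are tab-separated tables of monthly
death counts stratified by Census Region and Gender, with cells below ten
rendered as the literal token "Suppressed" and a trailing Notes block whose
lines begin with "---". Final data (1999-2020) and provisional data (2018
onward) are merged at a caller-supplied cutoff month.

Opioid-related deaths are identified on the death certificate by an
underlying cause in the drug-poisoning X/Y ranges paired with at least one
contributing T code for narcotic poisoning.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SUPPRESSED_TOKEN = "Suppressed"
NOTES_PREFIX = "---"
EXPORT_COLUMNS = ["Census Region", "Gender", "Year", "Month", "Deaths"]

_ICD_RE = re.compile(r"^[A-Z][0-9]{2}[0-9]?$")


def normalize_icd10(code: str) -> str:
    """Canonicalise an ICD-10 code: uppercase, dot removed ("T40.1"->"T401").

    Raises ValueError for syntactically invalid codes. Matching is by exact
    normalized code, never by prefix, so T40.5 (cocaine) cannot collide
    with the T40.x narcotic set.
    """
    norm = str(code).strip().upper().replace(".", "")
    if not _ICD_RE.match(norm):
        raise ValueError(f"syntactically invalid ICD-10 code: {code!r}")
    return norm


def _expand_range(start: str, stop: str) -> list[str]:
    letter = start[0]
    return [f"{letter}{i:02d}" for i in range(int(start[1:]), int(stop[1:]) + 1)]


@dataclass(frozen=True)
class OpioidCodeRule:
    """Inclusion rule for opioid-related deaths.

    Underlying cause must fall in the drug-poisoning set (X40-44 accidental,
    X60-64 intentional self-poisoning, X85 assault, Y10-14 undetermined
    intent) AND at least one contributing cause must be a narcotic T code
    (T40.0 opium, .1 heroin, .2 other opioids, .3 methadone, .4 synthetic
    narcotics, .6 other/unspecified narcotics). Codes are stored normalized.
    """

    underlying: frozenset = field(default_factory=lambda: frozenset(
        _expand_range("X40", "X44") + _expand_range("X60", "X64")
        + ["X85"] + _expand_range("Y10", "Y14")))
    contributing: frozenset = field(default_factory=lambda: frozenset(
        ["T400", "T401", "T402", "T403", "T404", "T406"]))

    def __post_init__(self):
        if not self.underlying or not self.contributing:
            raise ValueError("code sets must be non-empty")
        for c in list(self.underlying) + list(self.contributing):
            normalize_icd10(c)

    def matches(self, underlying: str, contributing) -> bool:
        u = normalize_icd10(underlying)
        t = {normalize_icd10(c) for c in contributing}
        return u in self.underlying and bool(t & self.contributing)


def default_rule() -> OpioidCodeRule:
    return OpioidCodeRule()


# ---------------------------------------------------------------------------
# Export parsing and merging

def parse_wonder_export(path) -> pd.DataFrame:
    """Parse a WONDER-dialect TSV into a monthly count table.

    Returns a DataFrame with columns (region, gender, year, month, count,
    suppressed): ``count`` is a float (NaN where suppressed), ``suppressed``
    a bool. The trailing Notes block ("---"-prefixed lines) is skipped.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    body = []
    for line in lines:
        if line.startswith(NOTES_PREFIX):
            break  # Notes block: everything from here on is free text
        if line.strip():
            body.append(line)
    if not body:
        return _empty_table()
    header = body[0].split("\t")
    for col in EXPORT_COLUMNS:
        if col not in header:
            raise ValueError(f"malformed WONDER export header: missing column {col!r}")
    idx = {col: header.index(col) for col in EXPORT_COLUMNS}
    records = []
    for lineno, line in enumerate(body[1:], start=2):
        fields = line.split("\t")
        deaths_raw = fields[idx["Deaths"]].strip()
        suppressed = deaths_raw == SUPPRESSED_TOKEN
        if suppressed:
            count = np.nan
        else:
            count = float(deaths_raw)
            if count < 0:
                raise ValueError(f"negative death count at line {lineno}: {deaths_raw}")
            if count != int(count):
                raise ValueError(f"non-integer death count at line {lineno}: {deaths_raw}")
        records.append({
            "region": fields[idx["Census Region"]].strip(),
            "gender": fields[idx["Gender"]].strip(),
            "year": int(fields[idx["Year"]]),
            "month": int(fields[idx["Month"]]),
            "count": count,
            "suppressed": suppressed,
        })
    if not records:
        return _empty_table()
    return pd.DataFrame.from_records(records)


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame({
        "region": pd.Series(dtype=str), "gender": pd.Series(dtype=str),
        "year": pd.Series(dtype=int), "month": pd.Series(dtype=int),
        "count": pd.Series(dtype=float), "suppressed": pd.Series(dtype=bool),
    })


def _ym_key(df: pd.DataFrame) -> pd.Series:
    return df["year"] * 12 + df["month"]


def merge_final_provisional(final: pd.DataFrame, provisional: pd.DataFrame,
                            cutoff: tuple[int, int]) -> pd.DataFrame:
    """Merge final and provisional count tables at a cutoff (year, month).

    Months at or before the cutoff come from the final table (authoritative);
    months after come from provisional. A ``provenance`` column records the
    source of each row.
    """
    if cutoff is None:
        overlap = final.merge(provisional, on=["region", "gender", "year", "month"],
                              suffixes=("_f", "_p"))
        disagree = overlap[(overlap["count_f"] != overlap["count_p"])
                           & ~(overlap["count_f"].isna() & overlap["count_p"].isna())]
        if len(disagree):
            r = disagree.iloc[0]
            raise ValueError(
                "conflicting counts with no cutoff rule, e.g. "
                f"{r['region']}/{r['gender']} {int(r['year'])}-{int(r['month']):02d}: "
                f"final={r['count_f']} provisional={r['count_p']}")
        cut_val = np.inf
    else:
        cut_val = cutoff[0] * 12 + cutoff[1]
    keep_final = final[_ym_key(final) <= cut_val].copy()
    keep_final["provenance"] = "final"
    keep_prov = provisional[_ym_key(provisional) > cut_val].copy()
    keep_prov["provenance"] = "provisional"
    merged = pd.concat([keep_final, keep_prov], ignore_index=True)
    merged = merged.sort_values(["region", "gender", "year", "month"],
                                ignore_index=True)
    dup = merged.duplicated(["region", "gender", "year", "month"])
    if dup.any():
        r = merged[dup].iloc[0]
        raise ValueError(f"duplicate cell after merge: {r['region']}/{r['gender']} "
                         f"{int(r['year'])}-{int(r['month']):02d}")
    return merged


# ---------------------------------------------------------------------------
# Record-level filtering and aggregation

def filter_opioid_deaths(certificates: pd.DataFrame,
                         rule: OpioidCodeRule | None = None) -> pd.DataFrame:
    """Keep death certificates meeting the opioid inclusion rule.

    ``certificates`` needs columns ``underlying_cause`` (one code) and
    ``contributing_causes`` (list of codes, possibly empty, or a
    ';'-separated string). A certificate with several qualifying T codes is
    kept once. Pure predicate: order-independent and idempotent.
    """
    rule = rule or default_rule()
    mask = []
    for i, row in enumerate(certificates.itertuples(index=False)):
        contributing = row.contributing_causes
        if isinstance(contributing, str):
            contributing = [c for c in contributing.split(";") if c]
        try:
            mask.append(rule.matches(row.underlying_cause, contributing))
        except ValueError as exc:
            raise ValueError(f"certificate {i}: {exc}") from None
    return certificates[np.asarray(mask, dtype=bool)].reset_index(drop=True)


def aggregate_over_gender(table: pd.DataFrame,
                          treat_missing_as_zero: bool = False) -> pd.DataFrame:
    """Sum gender strata into region-level monthly counts.

    Suppressed (missing) cells make the sum undefined and raise, unless the
    caller opts into ``treat_missing_as_zero``. A gender absent from a
    region-month entirely also raises, naming the missing stratum.
    """
    genders = sorted(table["gender"].unique())
    out_rows = []
    for (region, year, month), grp in table.groupby(["region", "year", "month"], sort=True):
        present = set(grp["gender"])
        missing = set(genders) - present
        if missing:
            raise ValueError(f"missing stratum {sorted(missing)} for "
                             f"{region} {year}-{month:02d}")
        if grp["suppressed"].any() and not treat_missing_as_zero:
            raise ValueError(f"suppressed cell in sum for {region} {year}-{month:02d}; "
                             "pass treat_missing_as_zero=True to override")
        count = grp["count"].fillna(0).sum() if treat_missing_as_zero else grp["count"].sum()
        out_rows.append({"region": region, "gender": "All", "year": year,
                         "month": month, "count": count, "suppressed": False})
    out = pd.DataFrame(out_rows)
    if "provenance" in table.columns:
        prov = table.groupby(["region", "year", "month"])["provenance"].first().reset_index()
        out = out.merge(prov, on=["region", "year", "month"], how="left")
    return out


def write_count_table(table: pd.DataFrame, path) -> None:
    """Persist a normalized monthly count table as CSV."""
    cols = ["region", "gender", "year", "month", "count", "suppressed"]
    if "provenance" in table.columns:
        cols.append("provenance")
    table[cols].to_csv(path, index=False)


def read_count_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["suppressed"] = df["suppressed"].astype(bool)
    return df
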