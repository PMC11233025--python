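"""Synthetic mortality data with a known piecewise-linear ITS truth.

The generator inverts the analysis: a true coefficient vector per stratum
defines the expected monthly death rate through the same design matrix the
model fits, expected counts follow from the interpolated population, and
Poisson noise (or optional Gaussian/AR(1) rate noise, or none) produces the
observed counts. Record-level death certificates and WONDER-dialect file
pairs are derived from the counts so that every ingest stage can be
exercised offline, with the truth available for parameter-recovery tests.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import demography
from .design import Timeline, build_design_matrix, default_timeline, monthly_index
from .wonder import EXPORT_COLUMNS, NOTES_PREFIX, SUPPRESSED_TOKEN

NOISE_KINDS = ("poisson-counts", "gaussian-rate", "none")


@dataclass
class TrueModel:
    """Data-generating truth: timeline plus per-stratum coefficients.

    ``coefficients`` maps (region, gender) to a vector in the design-column
    order of the timeline (intercept and level shifts in deaths per 100,000;
    slopes in deaths per 100,000 per month). ``gaussian_sd`` applies only to
    gaussian-rate noise; ``ar1_rho`` > 0 adds AR(1) serial correlation to
    that rate noise, probing the independence assumption of the fit.
    """

    timeline: Timeline
    coefficients: dict[tuple[str, str], np.ndarray]
    noise: str = "poisson-counts"
    gaussian_sd: float = 0.05
    ar1_rho: float = 0.0

    def __post_init__(self):
        if self.noise not in NOISE_KINDS:
            raise ValueError(f"unknown noise kind {self.noise!r}; choose from {NOISE_KINDS}")
        ncols = len(self.timeline.column_names())
        for stratum, beta in self.coefficients.items():
            beta = np.asarray(beta, dtype=float)
            if beta.shape != (ncols,):
                raise ValueError(f"stratum {stratum}: coefficient vector has length "
                                 f"{beta.size}, timeline implies {ncols} columns")
            self.coefficients[stratum] = beta

    @property
    def strata(self) -> list[tuple[str, str]]:
        return sorted(self.coefficients)

    def expected_rate(self, t) -> dict[tuple[str, str], np.ndarray]:
        """Noise-free expected rate per stratum over month indices ``t``."""
        X = build_design_matrix(np.asarray(t, dtype=int), self.timeline).to_numpy()
        return {s: X @ beta for s, beta in self.coefficients.items()}

    def to_yaml(self, path) -> None:
        data = {
            "timeline": [{"name": e.name, "date": e.date.isoformat(),
                          "immediate": e.immediate, "sustained": e.sustained}
                         for e in self.timeline],
            "noise": self.noise,
            "gaussian_sd": self.gaussian_sd,
            "ar1_rho": self.ar1_rho,
            "coefficients": [{"region": r, "gender": g,
                              "beta": [float(x) for x in beta]}
                             for (r, g), beta in sorted(self.coefficients.items())],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TrueModel":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        timeline = Timeline([
            _mk_intervention(item) for item in data["timeline"]])
        coefs = {(c["region"], c["gender"]): np.asarray(c["beta"], dtype=float)
                 for c in data["coefficients"]}
        return cls(timeline=timeline, coefficients=coefs, noise=data["noise"],
                   gaussian_sd=data.get("gaussian_sd", 0.05),
                   ar1_rho=data.get("ar1_rho", 0.0))


def _mk_intervention(item):
    from .design import Intervention
    return Intervention(name=item["name"],
                        date=_dt.date.fromisoformat(str(item["date"])),
                        immediate=bool(item["immediate"]),
                        sustained=bool(item["sustained"]))


def generate_population_table(strata, years, base_sizes, annual_growth=0.0) -> pd.DataFrame:
    """Annual July-1 population anchors, linear in the year.

    ``base_sizes`` and ``annual_growth`` may be scalars or dicts keyed by
    stratum; growth is in persons per year. Configurations driving any
    anchor to zero or below are rejected.
    """
    years = list(years)
    if len(years) > 1 and not np.all(np.diff(years) == 1):
        raise ValueError("years must be contiguous")
    rows = []
    for stratum in strata:
        base = base_sizes[stratum] if isinstance(base_sizes, dict) else base_sizes
        growth = annual_growth[stratum] if isinstance(annual_growth, dict) else annual_growth
        if base <= 0:
            raise ValueError(f"base population must be positive for {stratum}")
        for year in years:
            pop = base + growth * (year - years[0])
            if pop <= 0:
                raise ValueError(f"population for {stratum} hits {pop} in {year}; "
                                 "growth configuration rejected")
            rows.append({"region": stratum[0], "gender": stratum[1],
                         "year": int(year), "population": float(pop)})
    return pd.DataFrame(rows)


def simulate_monthly_counts(model: TrueModel, population: pd.DataFrame,
                            month_range: tuple, seed: int,
                            interpolation: str = "time") -> pd.DataFrame:
    """Simulate a per-stratum monthly mortality series with known truth.

    ``month_range`` is ((year, month), (year, month)) inclusive. Expected
    count at month t is mu_t * p_t / 100000 with mu_t from the true model;
    under poisson-counts noise the observed counts are Poisson draws with
    that mean. Identical seeds give identical output. Negative expected
    rates abort with the offending month named.
    """
    t0, t1 = monthly_index(month_range[0]), monthly_index(month_range[1])
    if t1 < t0:
        raise ValueError("month range end precedes start")
    t = np.arange(t0, t1 + 1)
    year_months = [((t0 - 1 + i) // 12 + 1999, (t0 - 1 + i) % 12 + 1) for i in range(len(t))]
    pops = demography.monthly_population(population, year_months, method=interpolation)
    mu_by_stratum = model.expected_rate(t)
    rng = np.random.default_rng(seed)
    frames = []
    for stratum in model.strata:
        region, gender = stratum
        mu = mu_by_stratum[stratum]
        if np.any(mu < 0):
            bad = int(np.argmax(mu < 0))
            y, m = year_months[bad]
            raise ValueError(f"expected rate is negative ({mu[bad]:.4f}) for "
                             f"{region}/{gender} in {y}-{m:02d}")
        pvals = pops[(pops["region"] == region) & (pops["gender"] == gender)]
        if len(pvals) != len(t):
            raise ValueError(f"population table does not cover {stratum} over the range")
        p = pvals["population"].to_numpy()
        lam = mu * p / 100000.0
        if model.noise == "poisson-counts":
            deaths = rng.poisson(lam).astype(float)
        elif model.noise == "gaussian-rate":
            eps = rng.normal(0.0, model.gaussian_sd, size=len(t))
            if model.ar1_rho:
                for i in range(1, len(eps)):
                    eps[i] += model.ar1_rho * eps[i - 1]
            deaths = np.maximum(0.0, (mu + eps)) * p / 100000.0
        else:
            deaths = lam
        frames.append(pd.DataFrame({
            "region": region, "gender": gender,
            "year": [ym[0] for ym in year_months],
            "month": [ym[1] for ym in year_months],
            "t": t, "date": pvals["date"].to_numpy(),
            "population": p, "expected_rate": mu, "deaths": deaths,
            "rate": 100000.0 * deaths / p,
        }))
    return pd.concat(frames, ignore_index=True)


# Default draw weights for opioid underlying causes and narcotic T codes;
# contaminant records use codes guaranteed to fail the inclusion rule.
_UNDERLYING_MIX = {"X42": 0.55, "X44": 0.20, "X41": 0.05, "X64": 0.10,
                   "Y12": 0.05, "X85": 0.05}
_TCODE_MIX = {"T401": 0.25, "T402": 0.25, "T404": 0.35, "T403": 0.10, "T406": 0.05}
_BAD_UNDERLYING = ["W34", "X45", "R99", "I21"]
_BAD_TCODES = ["T510", "T424", "T509"]


def simulate_certificates(counts: pd.DataFrame, seed: int,
                          contaminant_fraction: float = 0.0,
                          underlying_mix: dict | None = None,
                          tcode_mix: dict | None = None) -> pd.DataFrame:
    """Expand monthly counts into record-level death certificates.

    Every counted death yields one certificate passing the opioid inclusion
    rule. Contaminants — records that must fail the rule, via a wrong
    underlying cause or no qualifying T code — are added so that they make
    up ``contaminant_fraction`` of all records; their number is
    round(total * f / (1 - f)) and they carry ``is_contaminant=True``.
    """
    if not 0 <= contaminant_fraction < 1:
        raise ValueError(f"contaminant fraction must be in [0, 1), got {contaminant_fraction}")
    umix = underlying_mix or _UNDERLYING_MIX
    tmix = tcode_mix or _TCODE_MIX
    rng = np.random.default_rng(seed)
    ucodes, uw = list(umix), np.array(list(umix.values())) / sum(umix.values())
    tcodes, tw = list(tmix), np.array(list(tmix.values())) / sum(tmix.values())

    deaths = counts["deaths"].to_numpy()
    if np.any(deaths != np.round(deaths)):
        raise ValueError("certificate simulation needs integer death counts")
    reps = deaths.astype(int)
    base = counts.loc[counts.index.repeat(reps),
                      ["region", "gender", "year", "month"]].reset_index(drop=True)
    n_base = len(base)
    base["underlying_cause"] = rng.choice(ucodes, size=n_base, p=uw)
    base["contributing_causes"] = rng.choice(tcodes, size=n_base, p=tw)
    extra = rng.random(n_base) < 0.2  # some certificates list a second, non-opioid T code
    base.loc[extra, "contributing_causes"] += ";T509"
    base["is_contaminant"] = False

    n_cont = int(round(n_base * contaminant_fraction / (1 - contaminant_fraction)))
    if n_cont:
        src = counts.sample(n=n_cont, replace=True, random_state=rng.integers(2**31))
        cont = src[["region", "gender", "year", "month"]].reset_index(drop=True)
        wrong_underlying = rng.random(n_cont) < 0.5
        cont["underlying_cause"] = np.where(
            wrong_underlying,
            rng.choice(_BAD_UNDERLYING, size=n_cont),
            rng.choice(ucodes, size=n_cont, p=uw))
        cont["contributing_causes"] = np.where(
            wrong_underlying,
            rng.choice(tcodes, size=n_cont, p=tw),
            rng.choice(_BAD_TCODES, size=n_cont))
        cont["is_contaminant"] = True
        base = pd.concat([base, cont], ignore_index=True)

    dates = demography.assign_month_end_dates(list(zip(base["year"], base["month"])))
    base.insert(0, "date", dates)
    return base


def write_wonder_fixture(series: pd.DataFrame, out_dir,
                         suppress_below: int = 10,
                         split: tuple[int, int] | None = None) -> tuple[str, str]:
    """Write a final/provisional WONDER-dialect file pair from a count series.

    Rows at or before ``split`` (year, month) go to ``final.txt``, the rest
    to ``provisional.txt`` — emulating the two CDC WONDER extracts merged at
    a cutoff. Counts below ``suppress_below`` are rendered as the literal
    "Suppressed" token, as in real exports. Each file ends with a
    "---"-prefixed Notes block that parsers must skip.
    """
    import os
    os.makedirs(out_dir, exist_ok=True)
    if split is None:
        split = (0, 0)
    split_val = split[0] * 12 + split[1]
    ym = series["year"] * 12 + series["month"]
    paths = {}
    for name, mask in (("final", ym <= split_val), ("provisional", ym > split_val)):
        path = os.path.join(out_dir, f"{name}.txt")
        with open(path, "w") as fh:
            fh.write("\t".join(EXPORT_COLUMNS) + "\n")
            for row in series[mask].itertuples(index=False):
                d = int(round(row.deaths))
                val = SUPPRESSED_TOKEN if d < suppress_below else str(d)
                fh.write(f"{row.region}\t{row.gender}\t{row.year}\t{row.month}\t{val}\n")
            fh.write(f"{NOTES_PREFIX}\n")
            fh.write(f"{NOTES_PREFIX} Notes: synthetic {name} extract; cells below "
                     f"{suppress_below} suppressed.\n")
        paths[name] = path
    return paths["final"], paths["provisional"]


# ---------------------------------------------------------------------------
# Default study scenario

#: Per-region coefficient vectors with magnitudes typical of regional
#: monthly opioid death rates (intercepts ~0.1-0.3 per 100,000, fentanyl-era
#: slope changes ~0.01, immediate pandemic level shifts ~0.3-0.5).
REGION_BETA = {
    "Northeast": [0.2729, 0.0018, -0.0509, 0.0045, -0.1043, 0.0150,
                  -0.0153, 0.3701, -0.0006, 0.0014],
    "Midwest": [0.1069, 0.0033, 0.0173, 0.0000, -0.0771, 0.0122,
                -0.0177, 0.5409, 0.0070, -0.0029],
    "South": [0.1920, 0.0032, -0.0111, -0.0036, -0.0713, 0.0110,
              -0.0082, 0.5231, 0.0178, -0.0160],
    "West": [0.2972, 0.0026, -0.0263, -0.0031, 0.0155, 0.0014,
             0.0076, 0.3132, 0.0210, -0.0246],
}

#: July-1 base populations (persons per gender stratum) of rough census-region size.
REGION_POPULATION = {"Northeast": 28e6, "Midwest": 34e6, "South": 57e6, "West": 36e6}

#: Male rates run well above female rates throughout the epidemic.
GENDER_FACTOR = {"Female": 0.6, "Male": 1.4}


def default_scenario(noise: str = "poisson-counts",
                     covid_scale: float = 1.0) -> TrueModel:
    """Region x gender truth echoing the study's timeline and magnitudes.

    ``covid_scale`` rescales the pandemic-era coefficients (COVID level and
    slope, CHW slope); 0 gives a null-pandemic scenario for testing that
    excess-death estimates concentrate at zero.
    """
    timeline = default_timeline()
    coefs = {}
    for region, beta in REGION_BETA.items():
        beta = np.asarray(beta, dtype=float)
        for gender, factor in GENDER_FACTOR.items():
            b = beta * factor
            b[7:10] *= covid_scale
            coefs[(region, gender)] = b
    return TrueModel(timeline=timeline, coefficients=coefs, noise=noise)


def default_population(years=range(1999, 2023)) -> pd.DataFrame:
    """Annual anchors for the default scenario (~0.8%/yr linear growth)."""
    strata = [(r, g) for r in REGION_POPULATION for g in GENDER_FACTOR]
    bases = {(r, g): REGION_POPULATION[r] for r, g in strata}
    growth = {(r, g): REGION_POPULATION[r] * 0.008 for r, g in strata}
    return generate_population_table(strata, list(years), bases, growth)
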