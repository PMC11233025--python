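"""End-to-end orchestration: simulate, ingest, fit, counterfactual, bootstrap, report.

Each stage is a plain function over DataFrames with CSV artifacts on disk,
so the CLI subcommands stay thin and every intermediate is inspectable and
re-readable by the package's own readers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__, demography, synthetic, wonder
from .bootstrap import BootstrapConfig, bootstrap_cumulative_excess, national_bootstrap
from .design import (REGIONS, Timeline, build_design_matrix, build_interaction_design,
                     default_timeline, monthly_index)
from .excess import COVID_START_T, counterfactual_predict, excess_series, zero_pandemic_columns
from .fit import coefficient_table, compute_diagnostics, fit_ols, predict_with_intervals

log = logging.getLogger("opioid_its")


def _parse_ym(value) -> tuple[int, int]:
    if isinstance(value, (tuple, list)):
        return int(value[0]), int(value[1])
    y, m = str(value).split("-")
    return int(y), int(m)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    final_counts: str
    provisional_counts: str
    population: str
    out_dir: str
    seed: int
    cutoff: tuple[int, int] = (2020, 12)
    start: tuple[int, int] = (1999, 1)
    end: tuple[int, int] = (2022, 10)
    model: str = "foundational"
    regions: tuple = REGIONS
    bootstrap_B: int = 1000
    interpolation: str = "time"
    timeline_file: str | None = None
    quantile_method: str = "linear"
    make_figures: bool = True

    def __post_init__(self):
        self.cutoff = _parse_ym(self.cutoff)
        self.start = _parse_ym(self.start)
        self.end = _parse_ym(self.end)
        if self.model not in ("foundational", "gender"):
            raise ValueError(f"unknown model variant {self.model!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def validate_files(self) -> None:
        for label in ("final_counts", "provisional_counts", "population"):
            path = getattr(self, label)
            if not os.path.exists(path):
                raise FileNotFoundError(f"{label} file does not exist: {path}")
        if self.timeline_file and not os.path.exists(self.timeline_file):
            raise FileNotFoundError(f"timeline file does not exist: {self.timeline_file}")

    def timeline(self) -> Timeline:
        return (Timeline.from_yaml(self.timeline_file) if self.timeline_file
                else default_timeline())


# ---------------------------------------------------------------------------
# Stages

def simulate_stage(out_dir, seed: int, model: synthetic.TrueModel | None = None,
                   population: pd.DataFrame | None = None,
                   month_range=((1999, 1), (2022, 10)),
                   suppress_below: int = 0,
                   split: tuple[int, int] = (2020, 12)) -> dict:
    """Write a complete synthetic input set: WONDER file pair, population
    CSV and the generating truth as YAML."""
    os.makedirs(out_dir, exist_ok=True)
    model = model or synthetic.default_scenario()
    if population is None:
        population = synthetic.default_population(
            range(month_range[0][0], month_range[1][0] + 1))
    series = synthetic.simulate_monthly_counts(model, population, month_range, seed=seed)
    final_path, prov_path = synthetic.write_wonder_fixture(
        series, out_dir, suppress_below=suppress_below, split=split)
    pop_path = os.path.join(out_dir, "population.csv")
    population.to_csv(pop_path, index=False)
    truth_path = os.path.join(out_dir, "truth.yaml")
    model.to_yaml(truth_path)
    series.to_csv(os.path.join(out_dir, "truth_series.csv"), index=False)
    return {"final": final_path, "provisional": prov_path,
            "population": pop_path, "truth": truth_path, "series": series}


def ingest_stage(config: RunConfig) -> pd.DataFrame:
    """Parse, merge, aggregate and rate-convert the input extracts.

    Returns the analysis-ready rate table: one row per stratum-month with
    deaths, interpolated population and the death rate per 100,000.
    """
    final = wonder.parse_wonder_export(config.final_counts)
    prov = wonder.parse_wonder_export(config.provisional_counts)
    merged = wonder.merge_final_provisional(final, prov, cutoff=config.cutoff)
    merged = merged[merged["region"].isin(config.regions)]
    if config.model == "foundational":
        merged = wonder.aggregate_over_gender(merged)
    if merged["suppressed"].any():
        bad = merged[merged["suppressed"]].iloc[0]
        raise ValueError("suppressed cell in analysis range: "
                         f"{bad['region']}/{bad['gender']} "
                         f"{int(bad['year'])}-{int(bad['month']):02d}")

    t0, t1 = monthly_index(config.start), monthly_index(config.end)
    year_months = [((t - 1) // 12 + 1999, (t - 1) % 12 + 1) for t in range(t0, t1 + 1)]
    pop_annual = demography.read_population_csv(config.population)
    if config.model == "foundational":
        pop_annual = (pop_annual.groupby(["region", "year"], as_index=False)["population"]
                      .sum().assign(gender="All"))
    pops = demography.monthly_population(pop_annual, year_months,
                                         method=config.interpolation)
    out = merged.merge(pops, on=["region", "gender", "year", "month"], how="inner")
    out["t"] = (out["year"] - 1999) * 12 + out["month"]
    out = out[(out["t"] >= t0) & (out["t"] <= t1)].copy()
    out = out.rename(columns={"count": "deaths"})
    out["rate"] = demography.compute_death_rate(out["deaths"], out["population"])
    return out.sort_values(["region", "gender", "t"], ignore_index=True)


def fit_stage(rates: pd.DataFrame, timeline: Timeline, region: str,
              model: str = "foundational"):
    """Fit the ITS regression for one region; returns (fit, design, frame)."""
    sub = rates[rates["region"] == region]
    if sub.empty:
        raise ValueError(f"no data for region {region!r}")
    if model == "gender":
        sub = sub.sort_values(["gender", "t"], ignore_index=True)
        X = build_interaction_design(sub, timeline)
    else:
        sub = sub.sort_values("t", ignore_index=True)
        X = build_design_matrix(sub["t"].to_numpy(), timeline)
        X.index = sub.index
    return fit_ols(X, sub["rate"].to_numpy()), X, sub


def excess_stage(fit, X: pd.DataFrame, sub: pd.DataFrame,
                 start_t: int = COVID_START_T) -> pd.DataFrame:
    """Counterfactual projection and excess series for one fitted region.

    For the gender variant the excess series is computed per stratum and
    summed over genders month by month.
    """
    zeroed = list(X.columns[X.columns.str.contains("COVID|CHW")])
    Xcf = zero_pandemic_columns(X, zeroed=zeroed)
    cf = counterfactual_predict(fit, Xcf, zeroed=zeroed)
    pieces = []
    for g in sub["gender"].unique():
        rows = sub.index[sub["gender"] == g]
        t_g = sub.loc[rows, "t"].to_numpy()
        obs = pd.Series(sub.loc[rows, "rate"].to_numpy(), index=t_g)
        cf_fit = pd.Series(cf.loc[rows, "fit"].to_numpy(), index=t_g)
        cf_lo = pd.Series(cf.loc[rows, "pi_lower"].to_numpy(), index=t_g)
        cf_hi = pd.Series(cf.loc[rows, "pi_upper"].to_numpy(), index=t_g)
        pop = pd.Series(sub.loc[rows, "population"].to_numpy(), index=t_g)
        es = excess_series(obs, cf_fit, pop, start_t=start_t)
        # excess-rate band: counterfactual PI shifted by the observed rate
        es["excess_rate_pi_lower"] = (obs - cf_hi).loc[es.index].to_numpy()
        es["excess_rate_pi_upper"] = (obs - cf_lo).loc[es.index].to_numpy()
        es["gender"] = g
        pieces.append(es.reset_index())
    return pd.concat(pieces, ignore_index=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the result bundle to config.out_dir."""
    config.validate_files()
    os.makedirs(config.out_dir, exist_ok=True)
    timeline = config.timeline()
    log.info("flags: interpolation=%s model=%s B=%d quantiles=%s robust_se=False",
             config.interpolation, config.model, config.bootstrap_B,
             config.quantile_method)

    rates = ingest_stage(config)
    rates_path = os.path.join(config.out_dir, "rates.csv")
    rates.to_csv(rates_path, index=False)

    results: dict = {"rates": rates, "fits": {}, "excess": {}, "bootstrap": {}}
    per_region_cum: dict[str, pd.Series] = {}
    boot_seed = np.random.SeedSequence(config.seed)
    region_seeds = boot_seed.spawn(len(config.regions))

    for region, rseed in zip(config.regions, region_seeds):
        try:
            fit, X, sub = fit_stage(rates, timeline, region, model=config.model)
            coefficient_table(fit).to_csv(
                os.path.join(config.out_dir, f"coefficients_{region}.csv"), index=False)
            diag = compute_diagnostics(fit, X)
            diag["observations"].to_csv(
                os.path.join(config.out_dir, f"diagnostics_{region}.csv"))
            pred = predict_with_intervals(fit, X)
            pred_out = pd.concat([sub[["region", "gender", "t"]], pred], axis=1)
            pred_out.to_csv(os.path.join(config.out_dir, f"predictions_{region}.csv"),
                            index=False)
            ex = excess_stage(fit, X, sub)
            ex.insert(0, "region", region)
            ex.to_csv(os.path.join(config.out_dir, f"excess_{region}.csv"), index=False)

            bcfg = BootstrapConfig(B=config.bootstrap_B,
                                   seed=int(rseed.generate_state(1)[0] % 2**31),
                                   quantile_method=config.quantile_method,
                                   variant="gender" if config.model == "gender"
                                   else "foundational")
            reps = bootstrap_cumulative_excess(sub, timeline, bcfg)
            ci = reps.ci()
            ci.to_csv(os.path.join(config.out_dir, f"cumulative_excess_ci_{region}.csv"))
            results["fits"][region] = fit
            results["excess"][region] = ex
            results["bootstrap"][region] = reps
            per_region_cum[region] = reps.point
        except Exception as exc:
            raise RuntimeError(f"pipeline stage failed for region {region!r}: {exc}") from exc

    national = national_bootstrap(results["bootstrap"])
    national.ci().to_csv(os.path.join(config.out_dir, "cumulative_excess_ci_National.csv"))
    results["national"] = national

    if config.make_figures:
        from . import report
        report.make_figures(config, timeline, rates, results)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "flags": {"interpolation": config.interpolation, "robust_se": False,
                  "B": config.bootstrap_B, "quantile_method": config.quantile_method},
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return results
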