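"""Poisson parametric bootstrap for cumulative excess opioid deaths.

Each of B replicates: (1) resample monthly death counts d*_t ~ Poisson(d_t)
at every timepoint, (2) recompute rates with the original interpolated
populations, (3) refit the ITS regression, (4) project the no-pandemic
counterfactual from the refitted coefficients, (5) accumulate excess deaths
s*_t into c*_t. Empirical quantiles of {c*_{t,b}} give per-month confidence
bands; regional replicate trajectories are summed replicate-by-replicate
for the national band.

Because the design matrix is identical across replicates, the OLS refit is
precomputed once as a pseudoinverse and applied to all replicate response
vectors at once — numerically identical to refitting each replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import Timeline, build_design_matrix, build_interaction_design
from .excess import COVID_START_T, zero_pandemic_columns


@dataclass
class BootstrapConfig:
    B: int = 1000
    seed: int | None = None
    levels: tuple[float, float] = (0.025, 0.975)
    quantile_method: str = "linear"
    variant: str = "foundational"  # or "gender"

    def __post_init__(self):
        if self.B < 2:
            raise ValueError(f"need at least 2 replicates, got B={self.B}")
        if not all(0 < q < 1 for q in self.levels):
            raise ValueError(f"quantile levels must lie strictly inside (0,1): {self.levels}")
        if self.variant not in ("foundational", "gender"):
            raise ValueError(f"unknown model variant {self.variant!r}")


@dataclass
class BootstrapReplicates:
    """Replicate cumulative-excess trajectories and their quantile bands."""

    months: pd.Index               # month indices t >= pandemic start
    c_star: np.ndarray             # shape (n_months, B)
    point: pd.Series               # cumulative excess from the observed data
    config: BootstrapConfig = field(repr=False, default=None)

    @property
    def B(self) -> int:
        return self.c_star.shape[1]

    def ci(self, levels=None, method=None) -> pd.DataFrame:
        levels = levels or self.config.levels
        method = method or self.config.quantile_method
        lo = np.quantile(self.c_star, levels[0], axis=1, method=method)
        hi = np.quantile(self.c_star, levels[1], axis=1, method=method)
        return pd.DataFrame({"point": self.point.to_numpy(),
                             "lower": lo, "upper": hi}, index=self.months)

    def to_frame(self) -> pd.DataFrame:
        """Replicate matrix as a month x replicate DataFrame."""
        return pd.DataFrame(self.c_star, index=self.months,
                            columns=[f"b{b}" for b in range(self.B)])


def poisson_resample(counts, seed_or_rng) -> np.ndarray:
    """Draw d*_t ~ Poisson(d_t) independently at each timepoint."""
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    return rng.poisson(counts)


def _excess_deaths_pipeline(pinv: np.ndarray, Xcf_post: np.ndarray,
                            y: np.ndarray, post: np.ndarray,
                            p_post: np.ndarray) -> np.ndarray:
    """Rates -> OLS coefficients -> counterfactual -> monthly excess deaths.

    ``y`` may be a (n,) vector or an (n, B) matrix of replicate responses;
    the result covers the post-pandemic rows only.
    """
    beta = pinv @ y
    ycf = Xcf_post @ beta
    r = y[post] - ycf
    if y.ndim == 2:
        return r * (p_post / 100000.0)[:, None]
    return r * p_post / 100000.0


def bootstrap_cumulative_excess(series: pd.DataFrame, timeline: Timeline,
                                config: BootstrapConfig,
                                start_t: int = COVID_START_T) -> BootstrapReplicates:
    """Run the five-step Poisson bootstrap for one Census Region.

    ``series`` holds the full analysis range for the region with columns
    ``t``, ``deaths``, ``population`` (and ``gender`` for the
    gender-stratified variant, both strata stacked). Populations are held
    fixed; only counts are resampled — at all timepoints, pre-pandemic
    months included. For the gender variant the fully interacted model is
    fitted to both strata and the per-gender excess trajectories are summed.
    """
    if config.seed is None:
        raise ValueError("bootstrap requires an explicit seed")
    rng = np.random.default_rng(config.seed)

    if config.variant == "gender":
        series = series.sort_values(["gender", "t"], ignore_index=True)
        X = build_interaction_design(series, timeline)
    else:
        series = series.sort_values("t", ignore_index=True)
        X = build_design_matrix(series["t"].to_numpy(), timeline)
        X.index = series.index

    d = series["deaths"].to_numpy(dtype=float)
    p = series["population"].to_numpy(dtype=float)
    if np.any(d < 0):
        raise ValueError("death counts must be non-negative")

    post = (series["t"] >= start_t).to_numpy()
    zeroed = list(X.columns[X.columns.str.contains("COVID|CHW")])
    Xcf = zero_pandemic_columns(X, zeroed=zeroed)
    X_np = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X_np)
    if rank < X_np.shape[1]:
        raise ValueError("design matrix is rank deficient; cannot bootstrap")
    pinv = np.linalg.pinv(X_np)
    Xcf_post = Xcf.to_numpy(dtype=float)[post]
    p_post = p[post]

    y_obs = 100000.0 * d / p
    s_point = _excess_deaths_pipeline(pinv, Xcf_post, y_obs, post, p_post)

    d_star = rng.poisson(lam=d[:, None], size=(len(d), config.B)).astype(float)
    y_star = 100000.0 * d_star / p[:, None]
    s_star = _excess_deaths_pipeline(pinv, Xcf_post, y_star, post, p_post)

    t_post = series.loc[post, "t"].to_numpy()
    if config.variant == "gender":
        # both gender strata contribute excess deaths in each month:
        # group-sum over genders before cumulating
        s_star = pd.DataFrame(s_star).groupby(t_post).sum().to_numpy()
        s_point = pd.Series(s_point).groupby(t_post).sum().to_numpy()
        months_ix = pd.Index(np.unique(t_post), name="t")
    else:
        months_ix = pd.Index(t_post, name="t")
    c_star = np.cumsum(s_star, axis=0)
    c_point = np.cumsum(s_point)

    return BootstrapReplicates(months=months_ix, c_star=c_star,
                               point=pd.Series(c_point, index=months_ix),
                               config=config)


def national_bootstrap(per_region: dict[str, BootstrapReplicates]) -> BootstrapReplicates:
    """Sum regional replicate trajectories into a national one.

    Replicate pairing is preserved: national c*_{t,b} is the sum of each
    region's replicate b (each drawn from its own independent stream), and
    the band is the quantiles of the summed replicates. The national point
    estimate is the sum of regional point estimates.
    """
    regions = list(per_region)
    if not regions:
        raise ValueError("no regions supplied")
    first = per_region[regions[0]]
    for name, rep in per_region.items():
        if rep.B != first.B:
            raise ValueError(f"region {name!r} has B={rep.B}, expected {first.B}")
        if not rep.months.equals(first.months):
            raise ValueError(f"region {name!r} months do not match")
    c_star = sum(per_region[r].c_star for r in regions)
    point = sum(per_region[r].point for r in regions)
    return BootstrapReplicates(months=first.months, c_star=c_star,
                               point=point.rename("national"), config=first.config)
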