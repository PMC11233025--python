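"""OLS fitting, inference, prediction intervals and diagnostics for the ITS model.

Backed by statsmodels; coefficients are in deaths per 100,000 (levels) or
per 100,000 per month (slopes). Standard errors are classical homoskedastic
ones by default, with an optional heteroskedasticity-robust variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

ALPHA = 0.05


@dataclass
class FitResult:
    """OLS estimates and inference for an ITS design."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    cov_params: pd.DataFrame
    resid: pd.Series
    fittedvalues: pd.Series
    df_resid: int
    nobs: int
    resid_std_err: float
    rsquared: float
    rsquared_adj: float
    _sm_results: object = None

    @property
    def significant(self) -> pd.Series:
        """Coefficient significance at the alpha = 0.05 level."""
        return self.pvalues < ALPHA

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        tcrit = scipy.stats.t.ppf(0.5 + level / 2, self.df_resid)
        return pd.DataFrame({
            "lower": self.params - tcrit * self.bse,
            "upper": self.params + tcrit * self.bse,
        })


def _check_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # identify an offending column: one whose removal keeps the rank
        for col in X.columns:
            if np.linalg.matrix_rank(X.drop(columns=[col]).to_numpy()) == rank:
                raise ValueError(f"design matrix is rank deficient; column {col!r} "
                                 "is collinear with the others")
        raise ValueError("design matrix is rank deficient")


def fit_ols(X: pd.DataFrame, y, robust: bool = False) -> FitResult:
    """Fit the ITS regression by ordinary least squares.

    Parameters
    ----------
    X : DataFrame
        Design matrix including the intercept column.
    y : array-like
        Observed monthly death rates, aligned with the rows of X.
    robust : bool
        If True, report HC3 heteroskedasticity-robust standard errors
        instead of the classical ones (HC3 behaves well with the
        high-leverage points of short post-intervention segments).
    """
    y = np.asarray(y, dtype=float)
    if X.shape[0] <= X.shape[1]:
        raise ValueError(f"need more observations ({X.shape[0]}) than "
                         f"columns ({X.shape[1]})")
    _check_rank(X)
    model = sm.OLS(y, X.to_numpy(dtype=float))
    res = model.fit(cov_type="HC3") if robust else model.fit()
    names = list(X.columns)
    idx = X.index
    return FitResult(
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        tvalues=pd.Series(res.tvalues, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        cov_params=pd.DataFrame(res.cov_params(), index=names, columns=names),
        resid=pd.Series(res.resid, index=idx),
        fittedvalues=pd.Series(res.fittedvalues, index=idx),
        df_resid=int(res.df_resid),
        nobs=int(res.nobs),
        resid_std_err=float(np.sqrt(res.mse_resid)),
        rsquared=float(res.rsquared),
        rsquared_adj=float(res.rsquared_adj),
        _sm_results=res,
    )


def predict_with_intervals(fit: FitResult, X_new: pd.DataFrame,
                           level: float = 0.95) -> pd.DataFrame:
    """Fitted values with pointwise confidence and prediction intervals.

    The CI reflects uncertainty in the mean response (vcov of the linear
    predictor); the PI additionally includes the residual variance, so it
    contains the CI pointwise.
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    missing = [c for c in fit.params.index if c not in X_new.columns]
    if missing:
        raise ValueError(f"prediction rows missing design columns {missing}")
    pred = fit._sm_results.get_prediction(X_new[fit.params.index].to_numpy(dtype=float))
    frame = pred.summary_frame(alpha=1 - level)
    return pd.DataFrame({
        "fit": frame["mean"].to_numpy(),
        "ci_lower": frame["mean_ci_lower"].to_numpy(),
        "ci_upper": frame["mean_ci_upper"].to_numpy(),
        "pi_lower": frame["obs_ci_lower"].to_numpy(),
        "pi_upper": frame["obs_ci_upper"].to_numpy(),
    }, index=X_new.index)


def compute_diagnostics(fit: FitResult, X: pd.DataFrame) -> dict:
    """Regression diagnostics: residual-vs-fitted, Q-Q data, Cook's distance
    and leverage.

    Returned as plain data (a per-observation DataFrame plus a Q-Q table)
    rather than figures, so the quantities are assertable. Leverages are the
    hat-matrix diagonal and sum to the number of model columns.
    """
    infl = OLSInfluence(fit._sm_results)
    per_obs = pd.DataFrame({
        "fitted": fit.fittedvalues.to_numpy(),
        "residual": fit.resid.to_numpy(),
        "leverage": infl.hat_matrix_diag,
        "cooks_distance": infl.cooks_distance[0],
    }, index=X.index)
    resid_sorted = np.sort(fit.resid.to_numpy())
    n = len(resid_sorted)
    theo = scipy.stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    qq = pd.DataFrame({"theoretical": theo, "sample": resid_sorted})
    return {"observations": per_obs, "qq": qq}


def coefficient_table(fit: FitResult) -> pd.DataFrame:
    """Per-coefficient summary (variable, estimate, SE, p-value)."""
    return pd.DataFrame({
        "variable": fit.params.index,
        "estimate": fit.params.to_numpy(),
        "se": fit.bse.to_numpy(),
        "p_value": fit.pvalues.to_numpy(),
    })
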