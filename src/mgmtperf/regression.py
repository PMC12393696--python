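"""OLS with heteroskedasticity-robust inference for the performance models.

Two model families: per-outcome regressions of each performance indicator on
the overall adjusted management score (unit-cost models additionally control
for the matching intervention's scale count), and the six-dimension model
whose explained variance feeds the decomposition stage. Listwise deletion is
applied per outcome and logged so that observation counts are traceable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    CollinearityError,
    DomainUnscorableError,
    InsufficientDataError,
    JoinError,
    MgmtPerfError,
)
from .synthetic import OUTCOMES, SCALE_FOR, UNIT_COST_OUTCOMES

HC_TYPES = ("HC0", "HC1", "HC2", "HC3")


@dataclass
class OlsFit:
    """A fitted OLS model with robust (sandwich) uncertainty."""

    outcome: str
    params: pd.Series
    bse: pd.Series  # robust standard errors
    pvalues: pd.Series  # two-sided, on n - k degrees of freedom
    nobs: int
    df_resid: float
    r2: float
    fvalue: float
    f_pvalue: float
    hc_type: str
    resid: np.ndarray
    fitted: np.ndarray

    @property
    def tvalues(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse


def fit_ols_robust(
    y, X: pd.DataFrame, hc_type: str = "HC1", outcome: str = "y"
) -> OlsFit:
    """Least squares with an HC sandwich covariance and t/F inference.

    p-values are two-sided on ``n - k`` degrees of freedom. ``hc_type`` is
    one of HC0..HC3; HC1 applies the ``n/(n-k)`` small-sample factor.
    """
    if hc_type not in HC_TYPES:
        raise MgmtPerfError(f"unknown hc_type {hc_type!r}; expected one of {HC_TYPES}")
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any() or np.isnan(X.to_numpy()).any():
        raise MgmtPerfError("fit_ols_robust requires complete cases; drop NaNs first")
    n, k = X.shape
    if n <= k:
        raise InsufficientDataError(f"need n > k; n={n}, k={k}")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < k:
        from scipy.linalg import qr

        _, _, piv = qr(X.to_numpy(), mode="economic", pivoting=True)
        raise CollinearityError([X.columns[j] for j in piv[rank:]])
    res = sm.OLS(y, X).fit(cov_type=hc_type, use_t=True)
    return OlsFit(
        outcome=outcome,
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        nobs=int(res.nobs),
        df_resid=float(res.df_resid),
        r2=float(res.rsquared),
        fvalue=float(res.fvalue) if res.df_model > 0 else np.nan,
        f_pvalue=float(res.f_pvalue) if res.df_model > 0 else np.nan,
        hc_type=hc_type,
        resid=np.asarray(res.resid),
        fitted=np.asarray(res.fittedvalues),
    )


def join_scores_to_panel(
    score_frame: pd.DataFrame, panel: pd.DataFrame
) -> pd.DataFrame:
    """Merge per-CBO scores onto CBO-year panel rows by cbo_id."""
    panel_ids = set(panel["cbo_id"])
    score_ids = set(score_frame["cbo_id"])
    unmatched = panel_ids - score_ids
    if unmatched:
        raise JoinError(
            f"{len(unmatched)} panel CBO id(s) missing from scores, e.g. "
            f"{sorted(unmatched)[:3]}"
        )
    return panel.merge(score_frame, on="cbo_id", how="left", validate="many_to_one")


def _design_for(
    merged: pd.DataFrame, outcome: str, regressors: list[str], scale_in_costs: bool
) -> tuple[np.ndarray, pd.DataFrame, int]:
    cols = list(regressors)
    if scale_in_costs and outcome in UNIT_COST_OUTCOMES:
        cols.append(SCALE_FOR[outcome])
    needed = [outcome] + cols
    complete = merged.dropna(subset=needed)
    n_dropped = len(merged) - len(complete)
    y = complete[outcome].to_numpy(dtype=float)
    X = complete[cols].astype(float).copy()
    X.insert(0, "const", 1.0)
    return y, X, n_dropped


def fit_performance_models(
    adjusted_frame: pd.DataFrame,
    panel: pd.DataFrame,
    outcomes: list[str] | None = None,
    hc_type: str = "HC1",
    scale_in_costs: bool = True,
    score_column: str = "overall",
) -> list[OlsFit]:
    """Per-outcome OLS of performance on the overall management score.

    Unit-cost outcomes additionally include the matching intervention's
    scale count. Listwise deletion is applied per outcome, so observation
    counts may differ across models.
    """
    outcomes = outcomes or OUTCOMES
    merged = join_scores_to_panel(adjusted_frame[["cbo_id", score_column]], panel)
    fits = []
    for outcome in outcomes:
        if outcome not in merged.columns:
            raise MgmtPerfError(f"outcome {outcome!r} missing from panel")
        y, X, _ = _design_for(merged, outcome, [score_column], scale_in_costs)
        fits.append(fit_ols_robust(y, X, hc_type=hc_type, outcome=outcome))
    return fits


def fit_six_dimension_model(
    adjusted_frame: pd.DataFrame,
    panel: pd.DataFrame,
    outcome: str,
    domains: list[str],
    hc_type: str = "HC1",
    scale_in_costs: bool = True,
) -> OlsFit:
    """OLS of one outcome on the six adjusted domain scores (+ scale for costs)."""
    missing = [d for d in domains if d not in adjusted_frame.columns]
    if missing:
        raise DomainUnscorableError(f"adjusted scores lack domain columns {missing}")
    merged = join_scores_to_panel(adjusted_frame[["cbo_id"] + domains], panel)
    if outcome not in merged.columns:
        raise MgmtPerfError(f"outcome {outcome!r} missing from panel")
    y, X, _ = _design_for(merged, outcome, list(domains), scale_in_costs)
    return fit_ols_robust(y, X, hc_type=hc_type, outcome=outcome)


def table2_frame(fits: list[OlsFit], score_column: str = "overall") -> pd.DataFrame:
    """Arrange per-outcome fits into a coefficient/SE/N summary table."""
    rows = {}
    for fit in fits:
        rows[fit.outcome] = {
            "management_coef": fit.params[score_column],
            "management_se": fit.bse[score_column],
            "management_p": fit.pvalues[score_column],
            "intercept": fit.params["const"],
            "intercept_se": fit.bse["const"],
            "n": fit.nobs,
            "r2": fit.r2,
            "f_stat": fit.fvalue,
            "f_pvalue": fit.f_pvalue,
            "df_resid": fit.df_resid,
            "hc_type": fit.hc_type,
        }
    return pd.DataFrame(rows).T.rename_axis("outcome")
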