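"""Contextual adjustment of management scores and crude/adjusted comparison.

Each of the seven scores is regressed (OLS, robust SEs) on the contextual
covariates. The adjusted score is either the fitted value (the conditional
expectation given context — the default) or the residual, both exposed
because the two readings coexist in applied work. A two-sample
Kolmogorov-Smirnov comparison of crude vs adjusted distributions reports
both the raw sup-gap D and the sqrt(n1*n2/(n1+n2))-scaled statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kstwobign

from .errors import CollinearityError, InsufficientDataError, MgmtPerfError
from .index import ManagementScores
from .regression import OlsFit, fit_ols_robust

DEFAULT_CONTEXT_COVARIATES = [
    "country",
    "manager_degree",
    "years_open",
    "staff_n",
    "competitors_30min",
]


@dataclass
class ContextMatrix:
    """Per-CBO contextual covariates plus an intercept column."""

    cbo_ids: list[str]
    covariates: pd.DataFrame  # includes 'const'

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, columns: list[str] | None = None
    ) -> "ContextMatrix":
        if columns is None:
            columns = [c for c in DEFAULT_CONTEXT_COVARIATES if c in frame.columns]
        X = frame[columns].astype(float).copy()
        X.insert(0, "const", 1.0)
        matrix = cls(cbo_ids=list(frame["cbo_id"]), covariates=X)
        matrix.check_rank()
        return matrix

    def check_rank(self) -> None:
        X = self.covariates.to_numpy()
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # Identify dependent columns via pivoted QR on the column space.
            _, r, piv = _qr_pivot(X)
            dependent = [self.covariates.columns[j] for j in piv[rank:]]
            raise CollinearityError(dependent)


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, r, piv


@dataclass
class AdjustedScores:
    """Context-adjusted management scores in fitted or residual mode."""

    cbo_ids: list[str]
    adjusted: pd.DataFrame  # CBO x 7
    mode: str
    adjustment_fits: dict[str, OlsFit] = field(default_factory=dict)
    restandardized: bool = False

    def to_frame(self) -> pd.DataFrame:
        out = self.adjusted.copy()
        out.insert(0, "cbo_id", self.cbo_ids)
        return out


def adjust_scores(
    scores: ManagementScores | pd.DataFrame,
    context: ContextMatrix,
    mode: str = "fitted",
    restandardize: bool = False,
    hc_type: str = "HC1",
) -> AdjustedScores:
    """Adjust every score column for the contextual covariates.

    ``mode='fitted'`` returns X @ beta (conditional expectation given
    context); ``mode='residual'`` returns the OLS residuals. With
    ``restandardize=True`` each adjusted column is rescaled to mean 0, SD 1.
    """
    if mode not in ("fitted", "residual"):
        raise MgmtPerfError(f"unknown adjustment mode {mode!r}")
    score_frame = scores.to_frame() if isinstance(scores, ManagementScores) else scores
    if list(score_frame["cbo_id"]) != list(context.cbo_ids):
        score_frame = (
            score_frame.set_index("cbo_id").loc[context.cbo_ids].reset_index()
        )
    X = context.covariates
    n, p = X.shape
    if n <= p:
        raise InsufficientDataError(f"need n > p covariates; n={n}, p={p}")
    context.check_rank()

    adjusted = {}
    fits: dict[str, OlsFit] = {}
    for col in score_frame.columns:
        if col == "cbo_id":
            continue
        y = score_frame[col].to_numpy(dtype=float)
        fit = fit_ols_robust(y, X, hc_type=hc_type, outcome=col)
        fitted = X.to_numpy() @ fit.params.to_numpy()
        values = fitted if mode == "fitted" else y - fitted
        if restandardize:
            sd = np.std(values, ddof=0)  # population SD, matching score scaling
            if sd == 0.0:
                raise MgmtPerfError(
                    f"adjusted score {col!r} is constant; cannot restandardize"
                )
            values = (values - values.mean()) / sd
        adjusted[col] = values
        fits[col] = fit
    return AdjustedScores(
        cbo_ids=list(context.cbo_ids),
        adjusted=pd.DataFrame(adjusted),
        mode=mode,
        adjustment_fits=fits,
        restandardized=restandardize,
    )


def ks_compare(crude, adjusted) -> dict:
    """Two-sample KS comparison of crude vs adjusted score distributions.

    Returns the raw sup ECDF gap ``D`` (in [0, 1]), the scaled statistic
    ``T = sqrt(n1*n2/(n1+n2)) * D`` and the asymptotic two-sided p-value.
    """
    x = np.sort(np.asarray(crude, dtype=float))
    y = np.sort(np.asarray(adjusted, dtype=float))
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("KS comparison needs at least 2 points per sample")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / len(x)
    cdf_y = np.searchsorted(y, pooled, side="right") / len(y)
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    en = np.sqrt(len(x) * len(y) / (len(x) + len(y)))
    t = float(en * d)
    p = float(kstwobign.sf(t))
    return {"D": d, "T": t, "p_value": min(1.0, p), "n1": len(x), "n2": len(y)}
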