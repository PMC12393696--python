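"""Quantile regression of performance on management, with paired-bootstrap
tests of coefficient equality across quantiles.

Fits minimize the check loss rho_q(u) = u (q - 1{u<0}); asymptotic standard
errors use the kernel sparsity estimate, and bootstrap SEs come from
resampling whole rows with every requested quantile refit on the same
resample, so cross-quantile differences are properly paired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.regression.quantile_regression import QuantReg

from .errors import BootstrapError, InsufficientDataError, MgmtPerfError
from .synthetic import OUTCOMES, SCALE_FOR, UNIT_COST_OUTCOMES

DEFAULT_QUANTILES = (0.25, 0.50, 0.75, 0.95)
SMALL_TAIL_POINTS = 5  # q95 at n=90 leaves ~4.5 expected tail points -> flagged


def check_loss(u: np.ndarray, q: float) -> float:
    """Asymmetric absolute loss rho_q summed over residuals."""
    return float(np.sum(u * (q - (u < 0))))


def _lp_quantile(y: np.ndarray, X: np.ndarray, q: float) -> np.ndarray:
    """Exact check-loss minimizer via the standard LP formulation.

    min q 1'u + (1-q) 1'v  s.t.  X(b+ - b-) + u - v = y, u, v >= 0,
    solved with HiGHS, whose vertex selection is deterministic. Used in the
    bootstrap inner loop where IRLS can stall on degenerate resamples;
    agreement with the statsmodels solver is covered by tests.
    """
    from scipy.optimize import linprog

    n, k = X.shape
    c = np.concatenate([np.zeros(2 * k), q * np.ones(n), (1 - q) * np.ones(n)])
    A = np.hstack([X, -X, np.eye(n), -np.eye(n)])
    res = linprog(c, A_eq=A, b_eq=y, method="highs")
    if not res.success:
        raise MgmtPerfError(f"quantile LP failed: {res.message}")
    return res.x[:k] - res.x[k : 2 * k]


@dataclass
class QuantileFit:
    """One conditional-quantile fit."""

    outcome: str
    q: float
    params: pd.Series  # intercept + slopes
    bse: pd.Series  # kernel-sparsity asymptotic SEs
    nobs: int
    converged: bool
    objective: float  # check loss at the solution
    small_tail: bool = False


@dataclass
class CrossQuantileTest:
    """Paired-bootstrap test of slope equality between two quantiles."""

    outcome: str
    pair: tuple[float, float]
    difference: float
    bootstrap_se: float
    p_value: float
    n_replicates: int
    seed: int
    method: str = "wald"


def _tail_points(n: int, q: float) -> float:
    return n * min(q, 1.0 - q)


def fit_quantile(y, X: pd.DataFrame, q: float, outcome: str = "y") -> QuantileFit:
    """Fit the q-th conditional quantile of y on the design X.

    Degenerate outcomes (all values equal) yield a zero-slope fit with a
    warning; a quantile too extreme for the sample size (< 3 expected tail
    points) is flagged and warned about but still fit.
    """
    if not (0.0 < q < 1.0):
        raise MgmtPerfError(f"quantile level must be in (0, 1), got {q}")
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k:
        raise InsufficientDataError(f"need n > k; n={n}, k={k}")
    if np.isnan(y).any() or np.isnan(X.to_numpy()).any():
        raise MgmtPerfError("fit_quantile requires complete cases; drop NaNs first")

    small_tail = _tail_points(n, q) < SMALL_TAIL_POINTS
    if small_tail:
        warnings.warn(
            f"quantile q={q} leaves fewer than {SMALL_TAIL_POINTS} expected tail "
            f"points at n={n}; estimates may be unstable",
            UserWarning,
            stacklevel=2,
        )
    if np.ptp(y) == 0.0:
        warnings.warn(
            "outcome is constant; returning zero-slope quantile fit",
            UserWarning,
            stacklevel=2,
        )
        params = pd.Series(0.0, index=X.columns)
        if "const" in X.columns:
            params["const"] = y[0]
        return QuantileFit(
            outcome=outcome,
            q=q,
            params=params,
            bse=pd.Series(0.0, index=X.columns),
            nobs=n,
            converged=True,
            objective=0.0,
            small_tail=small_tail,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # IterationLimitWarning handled via flag
        model = QuantReg(y, X)
        res = model.fit(q=q)
    params = res.params.copy()
    objective = check_loss(y - X.to_numpy() @ params.to_numpy(), q)
    # Polish with the exact LP solution: IRLS can stop a few ulps short of
    # the optimal vertex, which matters at small n (at large n the LP costs
    # more than the residual inaccuracy is worth).
    if n <= 500:
        lp_params = _lp_quantile(y, X.to_numpy(dtype=float), q)
        lp_objective = check_loss(y - X.to_numpy() @ lp_params, q)
        if lp_objective < objective - 1e-12:
            params = pd.Series(lp_params, index=X.columns)
            objective = lp_objective
    converged = bool(getattr(res, "iterations", 0) < getattr(model, "max_iter", 1000))
    return QuantileFit(
        outcome=outcome,
        q=q,
        params=params,
        bse=res.bse.abs(),
        nobs=n,
        converged=converged,
        objective=objective,
        small_tail=small_tail,
    )


def bootstrap_quantile_tests(
    y,
    X: pd.DataFrame,
    quantiles=DEFAULT_QUANTILES,
    B: int = 500,
    seed: int = 0,
    slope_column: str | None = None,
    method: str = "wald",
    outcome: str = "y",
    max_failure_rate: float = 0.10,
) -> tuple[list[CrossQuantileTest], dict[float, float]]:
    """Paired bootstrap over rows; refits every quantile on each resample.

    Returns equality tests for each quantile pair plus per-quantile
    bootstrap SEs of the slope. ``method='wald'`` compares the observed
    slope difference with its replicate SD against a normal reference;
    ``method='percentile'`` derives the p-value from the replicate
    distribution of differences centered at the estimate.
    """
    if B < 100:
        raise MgmtPerfError(f"need B >= 100 bootstrap replicates, got {B}")
    if method not in ("wald", "percentile"):
        raise MgmtPerfError(f"unknown method {method!r}")
    quantiles = sorted(quantiles)
    if any(not (0.0 < q < 1.0) for q in quantiles):
        raise MgmtPerfError("all quantile levels must lie in (0, 1)")
    y = np.asarray(y, dtype=float)
    n = len(y)
    slope_column = slope_column or [c for c in X.columns if c != "const"][0]

    point = {q: fit_quantile(y, X, q, outcome=outcome).params[slope_column] for q in quantiles}

    rng = np.random.default_rng(seed)
    replicates = {q: [] for q in quantiles}
    failures = 0
    Xv = X.to_numpy(dtype=float)
    slope_idx = list(X.columns).index(slope_column)
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        Xb = Xv[idx]
        try:
            fits = {q: _lp_quantile(yb, Xb, q)[slope_idx] for q in quantiles}
        except Exception:
            failures += 1
            continue
        for q in quantiles:
            replicates[q].append(fits[q])
    if failures > max_failure_rate * B:
        raise BootstrapError(
            f"{failures}/{B} bootstrap replicates failed (> {max_failure_rate:.0%})"
        )

    boot_se = {q: float(np.std(replicates[q], ddof=1)) for q in quantiles}
    tests = []
    for i, qa in enumerate(quantiles):
        for qb in quantiles[:i]:
            diffs = np.asarray(replicates[qa]) - np.asarray(replicates[qb])
            delta = float(point[qa] - point[qb])
            se = float(np.std(diffs, ddof=1))
            if method == "wald":
                p = 2.0 * float(norm.sf(abs(delta) / se)) if se > 0 else float(delta == 0.0)
            else:
                centered = diffs - diffs.mean()
                p = float(np.mean(np.abs(centered) >= abs(delta)))
            tests.append(
                CrossQuantileTest(
                    outcome=outcome,
                    pair=(qa, qb),
                    difference=delta,
                    bootstrap_se=se,
                    p_value=min(1.0, p),
                    n_replicates=len(diffs),
                    seed=seed,
                    method=method,
                )
            )
    return tests, boot_se


@dataclass
class QuantileReport:
    """Per-outcome quantile fits, bootstrap SEs and the p-value triangle."""

    outcome: str
    fits: dict[float, QuantileFit]
    bootstrap_se: dict[float, float]
    tests: list[CrossQuantileTest]
    nobs: int
    crossings: list[tuple[float, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        quantiles = sorted(self.fits)
        p_lookup = {frozenset(t.pair): t.p_value for t in self.tests}
        rows = []
        slope_col = [c for c in self.fits[quantiles[0]].params.index if c != "const"][0]
        for q in quantiles:
            row = {
                "outcome": self.outcome,
                "q": q,
                "coef": self.fits[q].params[slope_col],
                "se_boot": self.bootstrap_se[q],
                "se_asymptotic": self.fits[q].bse[slope_col],
                "n": self.nobs,
                "small_tail": self.fits[q].small_tail,
            }
            for other in quantiles[:-1]:
                key = f"p_vs_q{int(round(other * 100))}"
                row[key] = p_lookup.get(frozenset((q, other)), np.nan) if other < q else np.nan
            rows.append(row)
        return pd.DataFrame(rows)


def quantile_table(
    adjusted_frame: pd.DataFrame,
    panel: pd.DataFrame,
    quantiles=DEFAULT_QUANTILES,
    B: int = 500,
    seed: int = 0,
    outcomes: list[str] | None = None,
    scale_in_costs: bool = True,
    score_column: str = "overall",
    method: str = "wald",
) -> dict[str, QuantileReport]:
    """Quantile fits and cross-quantile tests for every outcome."""
    from .regression import join_scores_to_panel

    outcomes = outcomes or OUTCOMES
    merged = join_scores_to_panel(adjusted_frame[["cbo_id", score_column]], panel)
    reports: dict[str, QuantileReport] = {}
    for outcome in outcomes:
        if outcome not in merged.columns:
            raise MgmtPerfError(f"outcome {outcome!r} missing from panel")
        cols = [score_column]
        if scale_in_costs and outcome in UNIT_COST_OUTCOMES:
            cols.append(SCALE_FOR[outcome])
        complete = merged.dropna(subset=[outcome] + cols)
        if complete[outcome].isna().all() or len(complete) == 0:
            raise MgmtPerfError(f"outcome {outcome!r} has no complete observations")
        y = complete[outcome].to_numpy(dtype=float)
        X = complete[cols].astype(float).copy()
        X.insert(0, "const", 1.0)
        fits = {q: fit_quantile(y, X, q, outcome=outcome) for q in quantiles}
        tests, boot_se = bootstrap_quantile_tests(
            y,
            X,
            quantiles=quantiles,
            B=B,
            seed=seed,
            slope_column=score_column,
            method=method,
            outcome=outcome,
        )
        # Flag (not fix) quantile crossings of fitted values at the mean design.
        xbar = X.mean().to_numpy()
        fitted_at_mean = {q: float(fits[q].params.to_numpy() @ xbar) for q in quantiles}
        crossings = [
            (qa, qb)
            for qa, qb in zip(sorted(quantiles), sorted(quantiles)[1:])
            if fitted_at_mean[qa] > fitted_at_mean[qb]
        ]
        if crossings:
            warnings.warn(
                f"quantile crossing detected for {outcome!r} at the mean design: "
                f"{crossings}",
                UserWarning,
                stacklevel=2,
            )
        reports[outcome] = QuantileReport(
            outcome=outcome,
            fits=fits,
            bootstrap_se=boot_se,
            tests=tests,
            nobs=len(complete),
            crossings=crossings,
        )
    return reports
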