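"""Shapley (Shorrocks) decomposition of regression explained variance.

Each regressor block ("player") receives its average marginal contribution
to the model R-squared over all subsets of the other players, weighted by
the Shapley factor |S|! (p - |S| - 1)! / p!. The allocation is
order-independent and sums exactly to the full-model R-squared. An optional
always-included block is supported as an alternative to treating a nuisance
covariate as a player; in the default pipeline the unit-cost scale count is
a genuine player whose share is computed but suppressed from display.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, MgmtPerfError
from .synthetic import OUTCOMES, SCALE_FOR, UNIT_COST_OUTCOMES

MAX_PLAYERS = 12

FIXED_PLAYER = "_fixed"


@dataclass
class ShapleyResult:
    """Per-player R-squared contributions for one outcome model."""

    outcome: str
    players: list[str]
    absolute_contribution: dict[str, float]
    relative_pct: dict[str, float]
    total_r2: float
    n_subsets_evaluated: int
    fixed_contribution: float = 0.0  # R2 of the always-included block alone

    def contributions_sum(self) -> float:
        return sum(self.absolute_contribution.values()) + self.fixed_contribution


def _r2(y: np.ndarray, blocks: list[np.ndarray]) -> float:
    """Centered R-squared of OLS of y on an intercept plus the blocks.

    Rank-deficient designs are handled by the least-norm solution; the
    projection (and hence R-squared) is well defined regardless.
    """
    n = len(y)
    if not blocks:
        return 0.0
    X = np.column_stack([np.ones(n)] + blocks)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise MgmtPerfError("outcome is constant; R-squared undefined")
    return 1.0 - float(np.sum(resid**2)) / tss


def shapley_r2(
    y,
    players: dict[str, np.ndarray],
    fixed: np.ndarray | None = None,
    outcome: str = "y",
) -> ShapleyResult:
    """Decompose model R-squared across regressor blocks.

    ``players`` maps a player name to an (n,) or (n, k) regressor block.
    ``fixed`` is an always-included block; its own R-squared (fit alone with
    an intercept) is reported as ``fixed_contribution`` so that player
    contributions plus the fixed contribution add up to the full-model
    R-squared.
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise MgmtPerfError("shapley_r2 requires complete cases")
    names = list(players)
    p = len(names)
    if p == 0:
        raise MgmtPerfError("need at least one player")
    if p > MAX_PLAYERS:
        raise MgmtPerfError(f"too many players ({p} > {MAX_PLAYERS}); 2^p fits required")
    blocks = {}
    for name in names:
        block = np.asarray(players[name], dtype=float)
        if block.ndim == 1:
            block = block[:, None]
        if len(block) != len(y):
            raise MgmtPerfError(f"player {name!r} has {len(block)} rows, y has {len(y)}")
        blocks[name] = block
    fixed_blocks: list[np.ndarray] = []
    if fixed is not None:
        fb = np.asarray(fixed, dtype=float)
        if fb.ndim == 1:
            fb = fb[:, None]
        fixed_blocks = [fb]
    if len(y) <= 1 + sum(b.shape[1] for b in blocks.values()) + sum(
        b.shape[1] for b in fixed_blocks
    ):
        raise InsufficientDataError("more regressors than observations in full model")

    # R-squared of every subset, cached by frozenset of player names.
    cache: dict[frozenset, float] = {}

    def subset_r2(subset: frozenset) -> float:
        if subset not in cache:
            cache[subset] = _r2(y, fixed_blocks + [blocks[m] for m in sorted(subset)])
        return cache[subset]

    contributions = {name: 0.0 for name in names}
    others = {name: [m for m in names if m != name] for name in names}
    for name in names:
        for size in range(p):
            weight = factorial(size) * factorial(p - size - 1) / factorial(p)
            for combo in combinations(others[name], size):
                s = frozenset(combo)
                contributions[name] += weight * (subset_r2(s | {name}) - subset_r2(s))

    fixed_r2 = subset_r2(frozenset())  # fixed block alone (0 when no fixed block)
    total = subset_r2(frozenset(names))
    if total <= 0.0:
        relative = {name: float("nan") for name in names}
    else:
        relative = {name: 100.0 * contributions[name] / total for name in names}
    return ShapleyResult(
        outcome=outcome,
        players=names,
        absolute_contribution=contributions,
        relative_pct=relative,
        total_r2=total,
        n_subsets_evaluated=len(cache),
        fixed_contribution=fixed_r2,
    )


SCALE_PLAYER = "scale"


def shapley_table(
    adjusted_frame: pd.DataFrame,
    panel: pd.DataFrame,
    domains: list[str],
    outcomes: list[str] | None = None,
    scale_in_costs: bool = True,
    scale_mode: str = "player",
    show_fixed_player: bool = False,
) -> tuple[pd.DataFrame, dict[str, ShapleyResult]]:
    """Decomposition of every outcome model; rows = domains, cols = outcomes.

    Unit-cost models include the intervention scale count — by default as a
    seventh player whose share is computed but omitted from the displayed
    table (so unit-cost columns sum to less than 100 whenever the scale
    share is positive); ``scale_mode='fixed'`` instead partials the scale
    block into every subset model. ``show_fixed_player=True`` appends the
    suppressed share as an extra row.
    """
    from .regression import join_scores_to_panel

    if scale_mode not in ("player", "fixed"):
        raise MgmtPerfError(f"unknown scale_mode {scale_mode!r}")
    outcomes = outcomes or OUTCOMES
    merged = join_scores_to_panel(adjusted_frame[["cbo_id"] + domains], panel)
    results: dict[str, ShapleyResult] = {}
    table = pd.DataFrame(index=domains + ([SCALE_PLAYER] if show_fixed_player else []))
    for outcome in outcomes:
        if outcome not in merged.columns:
            raise MgmtPerfError(f"outcome {outcome!r} missing from panel")
        use_scale = scale_in_costs and outcome in UNIT_COST_OUTCOMES
        needed = [outcome] + domains + ([SCALE_FOR[outcome]] if use_scale else [])
        complete = merged.dropna(subset=needed)
        y = complete[outcome].to_numpy(dtype=float)
        players = {d: complete[d].to_numpy(dtype=float) for d in domains}
        fixed = None
        if use_scale:
            scale_block = complete[SCALE_FOR[outcome]].to_numpy(dtype=float)
            if scale_mode == "player":
                players[SCALE_PLAYER] = scale_block
            else:
                fixed = scale_block
        result = shapley_r2(y, players, fixed=fixed, outcome=outcome)
        results[outcome] = result
        col = [result.relative_pct.get(d, np.nan) for d in domains]
        if show_fixed_player:
            col.append(result.relative_pct.get(SCALE_PLAYER, np.nan))
        table[outcome] = col
    return table, results
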