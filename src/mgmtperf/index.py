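"""Management index construction.

Binary practice items are z-scored per column, and each domain (and the
overall index) is summarized by a GLS-efficient weighted average: weights
proportional to the row sums of the inverse item covariance matrix, so that
highly redundant items are down-weighted. Zero-variance items are dropped,
never imputed. Ill-conditioned covariance blocks receive a recorded ridge
term before inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainUnscorableError, MgmtPerfError, NumericalError, ParseError

DEFAULT_COND_THRESHOLD = 1e10
OVERALL = "overall"


@dataclass
class PracticeMatrix:
    """CBO x item binary matrix with a domain assignment per item."""

    cbo_ids: list[str]
    items: pd.DataFrame  # index-free, one 0/1 column per item
    domain_map: dict[str, str]  # item column -> domain name
    binary: bool = True  # False admits affinely transformed item columns

    def __post_init__(self):
        if len(set(self.cbo_ids)) != len(self.cbo_ids):
            raise ParseError("duplicate CBO identifiers in practice matrix")
        missing = [c for c in self.items.columns if c not in self.domain_map]
        if missing:
            raise ParseError(f"items without a domain assignment: {missing}")
        values = self.items.to_numpy()
        if self.binary and not np.isin(values, (0, 1)).all():
            bad = np.argwhere(~np.isin(values, (0, 1)))[0]
            raise ParseError(
                "non-binary practice value",
                row=int(bad[0]),
                column=str(self.items.columns[bad[1]]),
            )

    @property
    def domains(self) -> list[str]:
        seen: dict[str, None] = {}
        for item in self.items.columns:
            seen.setdefault(self.domain_map[item], None)
        return list(seen)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, domain_map: dict[str, str]) -> "PracticeMatrix":
        items = frame.drop(columns=["cbo_id"])
        return cls(cbo_ids=list(frame["cbo_id"]), items=items, domain_map=domain_map)


@dataclass
class DomainWeighting:
    """Per-domain item weights from the inverse-covariance procedure."""

    domain: str
    kept_items: list[str]
    weights: np.ndarray  # sums to 1
    covariance_condition: float
    regularization_used: bool = False
    ridge: float = 0.0

    def __post_init__(self):
        if len(self.weights) != len(self.kept_items):
            raise MgmtPerfError("weight vector length does not match kept items")
        if abs(float(np.sum(self.weights)) - 1.0) > 1e-12:
            raise MgmtPerfError("weights do not sum to 1")


@dataclass
class ManagementScores:
    """Six domain scores plus the overall score, standardized across CBOs."""

    cbo_ids: list[str]
    domain_scores: pd.DataFrame  # CBO x 6
    overall_score: pd.Series
    weightings: dict[str, DomainWeighting] = field(default_factory=dict)
    dropped_items: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        out = self.domain_scores.copy()
        out[OVERALL] = self.overall_score.to_numpy()
        out.insert(0, "cbo_id", self.cbo_ids)
        return out

    @property
    def score_columns(self) -> list[str]:
        return list(self.domain_scores.columns) + [OVERALL]


def zscore_items(matrix: PracticeMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Demean and scale every item to sample SD 1 (n-1 denominator).

    Returns the z-scored matrix and the list of dropped zero-variance items.
    Raises :class:`DomainUnscorableError` if an entire domain is degenerate.
    """
    if len(matrix.cbo_ids) < 3:
        raise MgmtPerfError("need at least 3 CBOs to z-score items")
    values = matrix.items.astype(float)
    sds = values.std(ddof=1)
    dropped = list(sds.index[sds == 0.0])
    kept = values.drop(columns=dropped)
    for domain in matrix.domains:
        domain_items = [c for c in matrix.items.columns if matrix.domain_map[c] == domain]
        if all(c in dropped for c in domain_items):
            raise DomainUnscorableError(
                f"every item in domain {domain!r} has zero variance"
            )
    z = (kept - kept.mean()) / kept.std(ddof=1)
    return z, dropped


def gls_weights(
    z_block: pd.DataFrame,
    domain: str = "",
    ridge: str | float = "auto",
    cond_threshold: float = DEFAULT_COND_THRESHOLD,
) -> DomainWeighting:
    """GLS-efficient weights for one domain's z-scored items.

    The index is ``(1' S^-1 1)^-1 1' S^-1 x`` with S the sample covariance of
    the z-scored block, i.e. weights proportional to the row sums of S^-1.
    ``ridge='auto'`` adds ``lambda * I`` with geometrically escalating
    ``lambda`` until the condition number falls below ``cond_threshold``;
    ``ridge=0`` disables regularization and raises on singular covariance.
    """
    items = list(z_block.columns)
    if not items:
        raise MgmtPerfError(f"domain {domain!r} has no items")
    if len(items) == 1:
        return DomainWeighting(domain, items, np.array([1.0]), covariance_condition=1.0)

    cov = np.cov(z_block.to_numpy(), rowvar=False, ddof=1)
    cond = float(np.linalg.cond(cov))
    used_ridge = 0.0
    if ridge == "auto":
        lam = 1e-6 * float(np.mean(np.diag(cov)))
        while cond > cond_threshold:
            cov = cov + lam * np.eye(len(items))
            used_ridge += lam
            lam *= 10.0
            cond = float(np.linalg.cond(cov))
    elif float(ridge) > 0.0:
        used_ridge = float(ridge)
        cov = cov + used_ridge * np.eye(len(items))
        cond = float(np.linalg.cond(cov))
    if cond > 1e15 or not np.isfinite(cond):
        raise NumericalError(
            f"covariance matrix of domain {domain!r} is singular and "
            "regularization is disabled"
        )
    try:
        row_sums = np.linalg.solve(cov, np.ones(len(items)))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise NumericalError(f"cannot invert covariance of domain {domain!r}") from exc
    weights = row_sums / row_sums.sum()
    return DomainWeighting(
        domain=domain,
        kept_items=items,
        weights=weights,
        covariance_condition=cond,
        regularization_used=used_ridge > 0.0,
        ridge=used_ridge,
    )


def _standardize(x: np.ndarray) -> np.ndarray:
    # Population SD: keeps scores replication invariant (duplicating every
    # CBO row leaves each CBO's score unchanged), unlike the n-1 variant.
    sd = np.std(x, ddof=0)
    if sd == 0.0:
        raise NumericalError("score is constant across CBOs; cannot standardize")
    return (x - np.mean(x)) / sd


def compute_scores(
    matrix: PracticeMatrix,
    overall_mode: str = "items",
    ridge: str | float = "auto",
    cond_threshold: float = DEFAULT_COND_THRESHOLD,
) -> ManagementScores:
    """Compute the six domain scores and the overall management score.

    ``overall_mode='items'`` applies the GLS weighting to all items jointly;
    ``overall_mode='domains'`` applies it to the six domain scores instead.
    All seven scores are re-standardized to mean 0, SD 1 across CBOs.
    """
    if overall_mode not in ("items", "domains"):
        raise MgmtPerfError(f"unknown overall_mode {overall_mode!r}")
    z, dropped = zscore_items(matrix)
    weightings: dict[str, DomainWeighting] = {}
    raw_domain = {}
    for domain in matrix.domains:
        cols = [c for c in z.columns if matrix.domain_map[c] == domain]
        weighting = gls_weights(z[cols], domain=domain, ridge=ridge, cond_threshold=cond_threshold)
        weightings[domain] = weighting
        raw_domain[domain] = z[cols].to_numpy() @ weighting.weights

    domain_scores = pd.DataFrame(
        {d: _standardize(v) for d, v in raw_domain.items()}
    )

    if overall_mode == "items":
        weighting = gls_weights(z, domain=OVERALL, ridge=ridge, cond_threshold=cond_threshold)
        raw_overall = z.to_numpy() @ weighting.weights
    else:
        block = pd.DataFrame(raw_domain)
        weighting = gls_weights(block, domain=OVERALL, ridge=ridge, cond_threshold=cond_threshold)
        raw_overall = block.to_numpy() @ weighting.weights
    weightings[OVERALL] = weighting

    overall = pd.Series(_standardize(raw_overall), name=OVERALL)
    return ManagementScores(
        cbo_ids=list(matrix.cbo_ids),
        domain_scores=domain_scores,
        overall_score=overall,
        weightings=weightings,
        dropped_items=dropped,
    )
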