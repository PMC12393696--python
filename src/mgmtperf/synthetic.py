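"""Synthetic CBO panel generator.

Produces the three tables the analysis pipeline consumes — a binary
practice-item matrix, a context-covariate table and a CBO-year performance
panel — from a latent-quality model with known coefficients, so that every
downstream estimator can be checked against ground truth.

Mechanism: one latent quality draw ``z ~ N(0, 1)`` per CBO drives (a) each
binary practice item through a logit link, (b) the context covariates
through linear shifts, and (c) each performance outcome through a linear
model with optional location-scale (residual SD linear in ``z``) noise.
Management is generated once per CBO and repeated across fiscal years.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .errors import ConfigError, ParseError, ReferentialIntegrityError

# Canonical domain layout: six domains, 67 items total.
DEFAULT_DOMAIN_ITEMS: dict[str, int] = {
    "target_setting": 7,
    "performance_monitoring": 18,
    "people_management": 20,
    "operations_management": 11,
    "financial_management": 7,
    "community_engagement": 4,
}

OUTCOMES = ["uc_art", "uc_hts", "uc_sti", "n_art", "n_hts", "n_sti", "condoms_per_reached"]
UNIT_COST_OUTCOMES = ["uc_art", "uc_hts", "uc_sti"]
VOLUME_OUTCOMES = ["n_art", "n_hts", "n_sti"]
SCALE_FOR = {"uc_art": "scale_art", "uc_hts": "scale_hts", "uc_sti": "scale_sti"}

CONTEXT_COLUMNS = ["country", "manager_degree", "years_open", "staff_n", "competitors_30min"]

# Intercepts sit near the observed sample means of each indicator.
DEFAULT_INTERCEPTS = {
    "uc_art": 847.0,
    "uc_hts": 68.0,
    "uc_sti": 39.0,
    "n_art": 112.0,
    "n_hts": 1888.0,
    "n_sti": 2273.0,
    "condoms_per_reached": 275.0,
}

DEFAULT_BETA = {
    "uc_art": -200.0,
    "uc_hts": -15.0,
    "uc_sti": -8.0,
    "n_art": 25.0,
    "n_hts": 500.0,
    "n_sti": 400.0,
    "condoms_per_reached": 60.0,
}

DEFAULT_NOISE_SD = {
    "uc_art": 350.0,
    "uc_hts": 25.0,
    "uc_sti": 12.0,
    "n_art": 60.0,
    "n_hts": 900.0,
    "n_sti": 900.0,
    "condoms_per_reached": 150.0,
}

# Linear shift of each context covariate per unit of latent quality.
DEFAULT_CONTEXT_EFFECTS = {
    "manager_degree": 0.8,
    "years_open": 1.0,
    "staff_n": 1.5,
    "competitors_30min": 0.3,
}

# Negative marginal effect of intervention scale on its unit cost.
DEFAULT_SCALE_COEF = {"uc_art": -0.5, "uc_hts": -0.01, "uc_sti": -0.004}

# Lognormal medians/sigmas for per-intervention scale counts.
_SCALE_MEDIAN = {"scale_art": 110.0, "scale_hts": 1500.0, "scale_sti": 2000.0}
_SCALE_SIGMA = 0.6


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic CBO panel generator."""

    n_cbos: int = 45
    country_split: float = 30 / 45
    n_years: int = 2
    domain_item_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_DOMAIN_ITEMS)
    )
    latent_loading: float = 1.2
    context_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTEXT_EFFECTS)
    )
    beta_true: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    intercepts: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_INTERCEPTS))
    noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    quantile_scale: float = 0.0  # residual SD slope in z for unit-cost outcomes
    scale_coef: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SCALE_COEF))
    missing_art_rows: int = 1
    cost_floor: float = 0.5
    first_year: int = 2018
    # "latent": outcomes driven by the latent quality z itself;
    # "score": outcomes driven by the GLS-weighted overall score computed
    # from the generated items, so downstream regressions on that score are
    # free of measurement-error attenuation (used for calibration checks).
    outcome_driver: str = "latent"
    seed: int = 0

    def validate(self) -> None:
        if self.n_cbos < 3:
            raise ConfigError("n_cbos", f"must be >= 3, got {self.n_cbos}")
        if not (0.0 < self.country_split < 1.0):
            raise ConfigError("country_split", f"must lie in (0, 1), got {self.country_split}")
        if self.n_years < 1:
            raise ConfigError("n_years", f"must be >= 1, got {self.n_years}")
        for domain, count in self.domain_item_counts.items():
            if count < 1:
                raise ConfigError("domain_item_counts", f"domain {domain!r} has count {count}")
        for name, sd in self.noise_sd.items():
            if sd < 0:
                raise ConfigError("noise_sd", f"outcome {name!r} has negative SD {sd}")
        if self.missing_art_rows < 0:
            raise ConfigError("missing_art_rows", "must be >= 0")
        n_panel = self.n_cbos * self.n_years
        if self.missing_art_rows >= n_panel:
            raise ConfigError(
                "missing_art_rows", f"must be < panel size {n_panel}, got {self.missing_art_rows}"
            )
        if self.cost_floor <= 0:
            raise ConfigError("cost_floor", "must be strictly positive")
        unknown = set(self.beta_true) - set(OUTCOMES)
        if unknown:
            raise ConfigError("beta_true", f"unknown outcomes {sorted(unknown)}")
        if self.outcome_driver not in ("latent", "score"):
            raise ConfigError("outcome_driver", f"got {self.outcome_driver!r}")


@dataclass
class SyntheticBundle:
    """A generated dataset plus its generating truth."""

    practices: pd.DataFrame  # cbo_id + one 0/1 column per item
    context: pd.DataFrame  # cbo_id + context covariates
    panel: pd.DataFrame  # cbo_id, fiscal_year, outcomes, scale counts
    truth: dict

    @property
    def cbo_ids(self) -> list[str]:
        return list(self.practices["cbo_id"])

    @property
    def domain_map(self) -> dict[str, str]:
        return dict(self.truth["domain_map"])


def item_columns(domain_item_counts: Mapping[str, int]) -> dict[str, str]:
    """Map item column name -> domain, in canonical order."""
    mapping: dict[str, str] = {}
    for domain, count in domain_item_counts.items():
        for j in range(1, count + 1):
            mapping[f"{domain}_item{j:02d}"] = domain
    return mapping


def true_quantile_slope(truth: Mapping, outcome: str, q: float) -> float:
    """Analytic conditional-quantile slope of ``outcome`` in the latent score.

    Under the location-scale construction with Gaussian noise the slope at
    quantile ``q`` is ``beta + noise_sd * quantile_scale * Phi^{-1}(q)`` for
    unit-cost outcomes and constant ``beta`` otherwise.
    """
    beta = truth["beta_true"][outcome]
    if outcome in UNIT_COST_OUTCOMES:
        qs = truth["quantile_scale"]
        return beta + truth["noise_sd"][outcome] * qs * float(norm.ppf(q))
    return beta


def generate_cbo_panel(config: GeneratorConfig) -> SyntheticBundle:
    """Generate a fully reproducible synthetic CBO bundle from ``config``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cbos
    cbo_ids = [f"CBO{i:03d}" for i in range(1, n + 1)]

    # Latent management quality, one draw per CBO.
    z = rng.standard_normal(n)

    # --- context table ------------------------------------------------
    n_a = round(config.country_split * n)
    country = np.array([0] * n_a + [1] * (n - n_a))  # 0 = country A, 1 = country B
    eff = dict(DEFAULT_CONTEXT_EFFECTS)
    eff.update(config.context_effects)
    degree_logit = math.log(0.53 / 0.47) + eff["manager_degree"] * z
    manager_degree = (rng.random(n) < expit(degree_logit)).astype(int)
    years_open = np.clip(
        np.rint(5.0 + eff["years_open"] * z + rng.normal(0, 2.5, n)), 1, None
    ).astype(int)
    staff_n = np.clip(
        np.rint(7.0 + eff["staff_n"] * z + rng.normal(0, 3.0, n)), 2, None
    ).astype(int)
    competitors = np.clip(
        np.rint(2.0 + eff["competitors_30min"] * z + rng.normal(0, 1.2, n)), 0, 5
    ).astype(int)
    context = pd.DataFrame(
        {
            "cbo_id": cbo_ids,
            "country": country,
            "manager_degree": manager_degree,
            "years_open": years_open,
            "staff_n": staff_n,
            "competitors_30min": competitors,
        }
    )

    # --- practice matrix ----------------------------------------------
    domain_map = item_columns(config.domain_item_counts)
    items = list(domain_map)
    # Per-item difficulty thresholds on the latent scale; keeping them spread
    # independently of the loading means a large loading yields informative,
    # near-deterministic items rather than 67 copies of the same step.
    thresholds = rng.normal(0.0, 0.9, len(items))
    logits = config.latent_loading * (z[:, None] - thresholds[None, :])
    practice_values = (rng.random((n, len(items))) < expit(logits)).astype(int)
    practices = pd.DataFrame(practice_values, columns=items)
    practices.insert(0, "cbo_id", cbo_ids)

    # --- outcome driver ------------------------------------------------
    if config.outcome_driver == "score":
        from .index import PracticeMatrix, compute_scores

        matrix = PracticeMatrix.from_frame(practices, domain_map)
        driver = compute_scores(matrix).overall_score.to_numpy()
    else:
        driver = z

    # --- performance panel --------------------------------------------
    years = [config.first_year + t for t in range(config.n_years)]
    rows = []
    beta = dict(DEFAULT_BETA)
    beta.update(config.beta_true)
    icpt = dict(DEFAULT_INTERCEPTS)
    icpt.update(config.intercepts)
    sd = dict(DEFAULT_NOISE_SD)
    sd.update(config.noise_sd)
    scoef = dict(DEFAULT_SCALE_COEF)
    scoef.update(config.scale_coef)

    for i, cbo in enumerate(cbo_ids):
        for year in years:
            scale = {
                name: int(
                    max(1, round(med * math.exp(rng.normal(0.0, _SCALE_SIGMA))))
                )
                for name, med in _SCALE_MEDIAN.items()
            }
            row = {"cbo_id": cbo, "fiscal_year": year}
            for outcome in OUTCOMES:
                mu = icpt[outcome] + beta[outcome] * driver[i]
                if outcome in UNIT_COST_OUTCOMES:
                    sname = SCALE_FOR[outcome]
                    mu += scoef[outcome] * (scale[sname] - _SCALE_MEDIAN[sname])
                    sigma = sd[outcome] * max(0.05, 1.0 + config.quantile_scale * driver[i])
                    value = max(config.cost_floor, mu + sigma * rng.standard_normal())
                elif outcome in VOLUME_OUTCOMES:
                    value = int(max(0, round(mu + sd[outcome] * rng.standard_normal())))
                else:
                    value = max(1.0, mu + sd[outcome] * rng.standard_normal())
                row[outcome] = value
            row.update(scale)
            rows.append(row)
    panel = pd.DataFrame(rows)

    # Delete ART records (unit cost and persons on ART) in seeded rows to
    # force listwise deletion downstream.
    if config.missing_art_rows:
        drop_idx = rng.choice(len(panel), size=config.missing_art_rows, replace=False)
        panel.loc[drop_idx, ["uc_art", "n_art"]] = np.nan

    truth = {
        "z": {cbo: float(z[i]) for i, cbo in enumerate(cbo_ids)},
        "driver": {cbo: float(driver[i]) for i, cbo in enumerate(cbo_ids)},
        "outcome_driver": config.outcome_driver,
        "beta_true": beta,
        "intercepts": icpt,
        "noise_sd": sd,
        "quantile_scale": config.quantile_scale,
        "scale_coef": scoef,
        "latent_loading": config.latent_loading,
        "domain_map": domain_map,
        "seed": config.seed,
    }
    return SyntheticBundle(practices=practices, context=context, panel=panel, truth=truth)


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

PRACTICES_CSV = "practices.csv"
CONTEXT_CSV = "context.csv"
PERFORMANCE_CSV = "performance.csv"
TRUTH_JSON = "truth.json"


def write_bundle(bundle: SyntheticBundle, directory: str | Path) -> list[Path]:
    """Write the three CSV tables and the truth sidecar; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, frame in (
        (PRACTICES_CSV, bundle.practices),
        (CONTEXT_CSV, bundle.context),
        (PERFORMANCE_CSV, bundle.panel),
    ):
        path = directory / name
        frame.to_csv(path, index=False)
        paths.append(path)
    truth_path = directory / TRUTH_JSON
    truth_path.write_text(json.dumps(bundle.truth, indent=2, sort_keys=True))
    paths.append(truth_path)
    return paths


def _check_practices(practices: pd.DataFrame) -> None:
    if "cbo_id" not in practices.columns:
        raise ParseError("practice table lacks a 'cbo_id' column", column="cbo_id")
    dup = practices["cbo_id"][practices["cbo_id"].duplicated()]
    if len(dup):
        raise ParseError(
            f"duplicate CBO identifier {dup.iloc[0]!r} in practice table",
            row=int(dup.index[0]),
            column="cbo_id",
        )
    item_cols = [c for c in practices.columns if c != "cbo_id"]
    for col in item_cols:
        values = practices[col]
        bad = ~values.isin([0, 1])
        if bad.any():
            row = int(values.index[bad][0])
            raise ParseError(
                f"non-binary practice value {values.loc[row]!r}", row=row, column=col
            )


def read_bundle(directory: str | Path) -> SyntheticBundle:
    """Read a bundle written by :func:`write_bundle`, validating structure."""
    directory = Path(directory)
    practices = pd.read_csv(directory / PRACTICES_CSV)
    context = pd.read_csv(directory / CONTEXT_CSV)
    panel = pd.read_csv(directory / PERFORMANCE_CSV)
    truth = json.loads((directory / TRUTH_JSON).read_text())

    _check_practices(practices)
    dup = context["cbo_id"][context["cbo_id"].duplicated()]
    if len(dup):
        raise ParseError(
            f"duplicate CBO identifier {dup.iloc[0]!r} in context table",
            row=int(dup.index[0]),
            column="cbo_id",
        )
    known = set(practices["cbo_id"])
    unknown = panel.loc[~panel["cbo_id"].isin(known), "cbo_id"]
    if len(unknown):
        raise ReferentialIntegrityError(
            f"performance row {int(unknown.index[0])} references unknown CBO id "
            f"{unknown.iloc[0]!r}"
        )
    return SyntheticBundle(practices=practices, context=context, panel=panel, truth=truth)
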