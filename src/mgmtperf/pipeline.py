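"""End-to-end orchestration: simulate/load -> score -> adjust -> regress ->
decompose -> quantile, with a consolidated, reproducible report.

Every stochastic stage derives its seed deterministically from the global
seed, all tabular outputs are plain CSV/JSON, and the provenance block
records every data-dropping event (zero-variance items, ridge escalations,
listwise deletions) so reported observation counts are traceable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adjust import AdjustedScores, ContextMatrix, adjust_scores, ks_compare
from .errors import ConfigError
from .index import ManagementScores, PracticeMatrix, compute_scores
from .quantiles import DEFAULT_QUANTILES, quantile_table
from .regression import fit_performance_models, fit_six_dimension_model, table2_frame
from .shapley import shapley_table
from .synthetic import (
    CONTEXT_COLUMNS,
    OUTCOMES,
    GeneratorConfig,
    SyntheticBundle,
    generate_cbo_panel,
    read_bundle,
    write_bundle,
)

_STAGE_INDEX = {"simulate": 0, "bootstrap": 1}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    ss = np.random.SeedSequence((int(global_seed), _STAGE_INDEX[stage]))
    return int(ss.generate_state(1)[0])


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    data_dir: str | None = None  # read an existing bundle instead of simulating
    simulate: GeneratorConfig | None = None
    adjustment_mode: str = "fitted"
    restandardize: bool = True
    hc_type: str = "HC1"
    overall_mode: str = "items"
    quantiles: tuple = DEFAULT_QUANTILES
    bootstrap_reps: int = 500
    scale_in_costs: bool = True
    context_columns: list | None = None  # None -> all five context covariates
    make_figure: bool = True

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = GeneratorConfig(**sim)
        if cfg.adjustment_mode not in ("fitted", "residual"):
            raise ConfigError("adjustment_mode", f"got {cfg.adjustment_mode!r}")
        if cfg.bootstrap_reps < 100:
            raise ConfigError("bootstrap_reps", "must be >= 100")
        return cfg


@dataclass
class RunReport:
    """All pipeline outputs plus provenance."""

    bundle: SyntheticBundle
    scores: ManagementScores
    adjusted: AdjustedScores
    descriptives: pd.DataFrame
    ks: dict
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: dict
    provenance: dict


def descriptives(bundle: SyntheticBundle) -> pd.DataFrame:
    """Table-1-style summary: N, mean, median, min, max per key variable."""
    rows = []
    for col in CONTEXT_COLUMNS:
        series = bundle.context[col].dropna()
        rows.append(_summary_row(col, series, level="cbo"))
    for col in OUTCOMES:
        series = bundle.panel[col].dropna()
        rows.append(_summary_row(col, series, level="cbo-year"))
    return pd.DataFrame(rows).set_index("variable")


def _summary_row(name: str, series: pd.Series, level: str) -> dict:
    return {
        "variable": name,
        "level": level,
        "n": int(series.count()),
        "mean": float(series.mean()),
        "median": float(series.median()),
        "min": float(series.min()),
        "max": float(series.max()),
    }


def run_pipeline(config: RunConfig, outdir: str | Path) -> RunReport:
    """Run the full chain and write all stage outputs under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- data ----------------------------------------------------------
    if config.data_dir is not None:
        bundle = read_bundle(config.data_dir)
    else:
        sim = config.simulate or GeneratorConfig()
        sim.seed = stage_seed(config.seed, "simulate")
        bundle = generate_cbo_panel(sim)
        write_bundle(bundle, outdir / "data")

    # --- scores --------------------------------------------------------
    matrix = PracticeMatrix.from_frame(bundle.practices, bundle.domain_map)
    scores = compute_scores(matrix, overall_mode=config.overall_mode)
    scores.to_frame().to_csv(outdir / "scores.csv", index=False)
    weights_rows = []
    for domain, w in scores.weightings.items():
        for item, weight in zip(w.kept_items, w.weights):
            weights_rows.append(
                {"domain": domain, "item": item, "weight": float(weight)}
            )
    pd.DataFrame(weights_rows).to_csv(outdir / "weights.csv", index=False)

    # --- adjustment ----------------------------------------------------
    context = ContextMatrix.from_frame(bundle.context, columns=config.context_columns)
    adjusted = adjust_scores(
        scores,
        context,
        mode=config.adjustment_mode,
        restandardize=config.restandardize,
        hc_type=config.hc_type,
    )
    adjusted_frame = adjusted.to_frame()
    adjusted_frame.to_csv(outdir / "adjusted.csv", index=False)
    ks = ks_compare(
        scores.overall_score.to_numpy(), adjusted.adjusted["overall"].to_numpy()
    )
    (outdir / "ks.json").write_text(json.dumps(ks, indent=2, sort_keys=True))

    # --- descriptives --------------------------------------------------
    table1 = descriptives(bundle)
    table1.to_csv(outdir / "table1.csv")

    # --- mean regression -----------------------------------------------
    fits = fit_performance_models(
        adjusted_frame,
        bundle.panel,
        hc_type=config.hc_type,
        scale_in_costs=config.scale_in_costs,
    )
    table2 = table2_frame(fits)
    table2.to_csv(outdir / "table2.csv")

    # --- decomposition -------------------------------------------------
    domains = list(scores.domain_scores.columns)
    table3, shapley_results = shapley_table(
        adjusted_frame,
        bundle.panel,
        domains=domains,
        scale_in_costs=config.scale_in_costs,
    )
    table3.rename_axis("dimension").to_csv(outdir / "table3.csv")

    # --- quantile analysis ---------------------------------------------
    table4 = quantile_table(
        adjusted_frame,
        bundle.panel,
        quantiles=config.quantiles,
        B=config.bootstrap_reps,
        seed=stage_seed(config.seed, "bootstrap"),
        scale_in_costs=config.scale_in_costs,
    )
    table4_frame = pd.concat([r.to_frame() for r in table4.values()], ignore_index=True)
    table4_frame.to_csv(outdir / "table4.csv", index=False)

    # --- figure ---------------------------------------------------------
    if config.make_figure:
        _density_figure(
            scores.overall_score.to_numpy(),
            adjusted.adjusted["overall"].to_numpy(),
            outdir / "crude_vs_adjusted.png",
        )

    # --- provenance -----------------------------------------------------
    provenance = {
        "package_version": __version__,
        "config": _config_dict(config),
        "config_hash": _config_hash(config),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGE_INDEX},
        "dropped_items": scores.dropped_items,
        "ridge_events": {
            d: {"ridge": w.ridge, "condition": w.covariance_condition}
            for d, w in scores.weightings.items()
            if w.regularization_used
        },
        "listwise_deletion": {f.outcome: int(f.nobs) for f in fits},
        "n_cbos": len(bundle.cbo_ids),
        "n_panel_rows": int(len(bundle.panel)),
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))

    return RunReport(
        bundle=bundle,
        scores=scores,
        adjusted=adjusted,
        descriptives=table1,
        ks=ks,
        table2=table2,
        table3=table3,
        table4=table4,
        provenance=provenance,
    )


def report_hash(outdir: str | Path) -> str:
    """SHA-256 over all CSV/JSON outputs of a run, in sorted path order."""
    outdir = Path(outdir)
    digest = hashlib.sha256()
    for path in sorted(outdir.rglob("*")):
        if path.suffix in (".csv", ".json") and path.is_file():
            digest.update(path.relative_to(outdir).as_posix().encode())
            digest.update(path.read_bytes())
    return digest.hexdigest()


def _config_dict(config: RunConfig) -> dict:
    out = {
        k: v
        for k, v in vars(config).items()
        if k != "simulate"
    }
    out["quantiles"] = list(config.quantiles)
    if config.simulate is not None:
        sim = {}
        for k, v in vars(config.simulate).items():
            sim[k] = dict(v) if isinstance(v, dict) else v
        out["simulate"] = sim
    return out


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(_config_dict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _density_figure(crude: np.ndarray, adjusted: np.ndarray, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    grid = np.linspace(
        min(crude.min(), adjusted.min()) - 1.0,
        max(crude.max(), adjusted.max()) + 1.0,
        400,
    )
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for values, label, style in ((crude, "crude", "-"), (adjusted, "adjusted", "--")):
        if np.std(values) > 0:
            ax.plot(grid, gaussian_kde(values)(grid), style, label=label)
    ax.set_xlabel("overall management z-score")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
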