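# mgmtperf

Tools for studying how management practices relate to the performance of
community-based health facilities. The package turns a binary
management-practice survey into inverse-covariance-weighted (GLS) domain
scores, adjusts them for contextual characteristics, and links them to
facility performance indicators (unit costs, service volumes, outreach
quality) through robust OLS, a Shapley decomposition of explained variance,
and quantile regressions with paired-bootstrap cross-quantile tests. A
synthetic panel generator with known ground truth backs every estimator
with parameter-recovery checks.

## Modules

| Module | Purpose |
| --- | --- |
| `mgmtperf.synthetic` | Latent-quality generator for CBO panels (practice items, context covariates, performance panel) with CSV/JSON round-trip I/O |
| `mgmtperf.index` | Item z-scoring and GLS-efficient (inverse-covariance) domain/overall scores with ridge-stabilized inversion |
| `mgmtperf.adjust` | Contextual adjustment (fitted or residual mode) and crude-vs-adjusted Kolmogorov-Smirnov comparison |
| `mgmtperf.regression` | Heteroskedasticity-robust OLS (HC0–HC3) per-outcome and six-dimension models with per-outcome listwise deletion |
| `mgmtperf.shapley` | Exact Shapley/Shorrocks decomposition of model R² across regressor blocks |
| `mgmtperf.quantiles` | Check-loss quantile fits (IRLS with exact-LP polish), paired bootstrap SEs and cross-quantile equality tests |
| `mgmtperf.pipeline` | One-command orchestration with provenance (seeds, dropped items, ridge events, listwise-deletion log) |

## CLI

Each stage is independently runnable and exchanges plain CSV/JSON:

```bash
mgmtperf simulate --seed 1 --out data/
mgmtperf score    --practices data/practices.csv --out scores.csv
mgmtperf adjust   --scores scores.csv --context data/context.csv --out adjusted.csv
mgmtperf regress  --adjusted adjusted.csv --panel data/performance.csv --out table2.csv
mgmtperf shapley  --adjusted adjusted.csv --panel data/performance.csv --out table3.csv
mgmtperf quantile --adjusted adjusted.csv --panel data/performance.csv \
                  --q 0.25 --q 0.5 --q 0.75 --q 0.95 --B 500 --seed 1 --out table4.csv
```

or the whole chain at once, driven by a YAML config:

```bash
mgmtperf run-all --config run.yaml --seed 1 --out results/
```

which writes the simulated bundle, score and weight tables, adjusted scores,
the KS report, descriptive summaries, the three analysis tables, a
crude-vs-adjusted density figure and a provenance block. Reruns with the
same config are byte-identical.

## Notes on conventions

- Items are z-scored with the sample (n−1) SD; zero-variance items are
  dropped and reported, never imputed.
- Domain weights are proportional to the row sums of the inverse item
  covariance; near-singular covariances receive a geometrically escalating
  ridge that is always recorded in the weights sidecar/provenance.
- Final scores use population-SD standardization, which keeps scores
  invariant under replication of the CBO roster.
- Adjusted scores default to fitted values (conditional expectation given
  context); residual mode is a first-class alternative.
- The KS comparison reports both the raw sup-ECDF gap D and the
  sqrt(n1·n2/(n1+n2))-scaled statistic.
- Unit-cost models include the matching intervention's scale count; in the
  Shapley table that scale covariate is a seventh player whose share is
  computed but suppressed from display (so unit-cost columns sum to less
  than 100% when its share is positive).
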