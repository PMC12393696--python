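from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from mgmtperf import (
    GeneratorConfig,
    bootstrap_quantile_tests,
    fit_quantile,
    generate_cbo_panel,
    quantile_table,
    true_quantile_slope,
)
from mgmtperf.errors import MgmtPerfError
from mgmtperf.quantiles import _lp_quantile, check_loss


def design(x):
    frame = pd.DataFrame({"overall": np.asarray(x, dtype=float)})
    frame.insert(0, "const", 1.0)
    return frame


def vertex_enumeration_oracle(y, x, q):
    """Best check loss over every line through two distinct sample points."""
    best = np.inf
    best_params = None
    for i, j in combinations(range(len(y)), 2):
        if x[i] == x[j]:
            continue
        slope = (y[j] - y[i]) / (x[j] - x[i])
        intercept = y[i] - slope * x[i]
        loss = check_loss(y - (intercept + slope * x), q)
        if loss < best - 1e-12:
            best = loss
            best_params = (intercept, slope)
    return best, best_params


class TestFitQuantile:
    def test_exact_line_any_quantile(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = 1.0 + 2.0 * x
        for q in (0.25, 0.5, 0.75, 0.95):
            fit = fit_quantile(y, design(x), q)
            assert fit.objective == pytest.approx(0.0, abs=1e-8)
            assert fit.params["overall"] == pytest.approx(2.0, abs=1e-6)

    @pytest.mark.parametrize("q", [0.25, 0.5, 0.75])
    def test_six_point_toy_matches_vertex_enumeration(self, q):
        rng = np.random.default_rng(23)
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = 1.0 + 0.8 * x + rng.normal(0, 1.0, 6)
        fit = fit_quantile(y, design(x), q)
        best_loss, best_params = vertex_enumeration_oracle(y, x, q)
        assert fit.objective == pytest.approx(best_loss, abs=1e-6)
        assert fit.params["const"] == pytest.approx(best_params[0], abs=1e-4)
        assert fit.params["overall"] == pytest.approx(best_params[1], abs=1e-4)

    @pytest.mark.parametrize("q", [0.25, 0.5, 0.75])
    def test_lp_solver_matches_vertex_enumeration(self, q):
        rng = np.random.default_rng(29)
        x = rng.standard_normal(6)
        y = 0.5 - 1.2 * x + rng.normal(0, 0.7, 6)
        beta = _lp_quantile(y, design(x).to_numpy(), q)
        best_loss, _ = vertex_enumeration_oracle(y, x, q)
        assert check_loss(y - design(x).to_numpy() @ beta, q) == pytest.approx(
            best_loss, abs=1e-8
        )

    def test_lp_and_irls_solvers_agree(self):
        rng = np.random.default_rng(31)
        x = rng.standard_normal(80)
        y = 2.0 + 1.5 * x + rng.standard_normal(80)
        for q in (0.25, 0.5, 0.75):
            fit = fit_quantile(y, design(x), q)
            beta = _lp_quantile(y, design(x).to_numpy(), q)
            assert check_loss(y - design(x).to_numpy() @ beta, q) == pytest.approx(
                fit.objective, rel=1e-6
            )

    def test_median_slope_recovery_large_n(self):
        rng = np.random.default_rng(11)
        n = 2000
        x = rng.standard_normal(n)
        y = 1.0 + 0.8 * x + rng.standard_normal(n)  # symmetric noise about the line
        fit = fit_quantile(y, design(x), 0.5)
        assert fit.params["overall"] == pytest.approx(0.8, abs=0.05)

    def test_check_loss_not_worse_than_ols(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal(60)
        y = 1.0 + x + rng.standard_normal(60) * (1 + 0.5 * np.abs(x))
        X = design(x)
        ols_beta = np.linalg.lstsq(X.to_numpy(), y, rcond=None)[0]
        for q in (0.25, 0.5, 0.75, 0.95):
            fit = fit_quantile(y, X, q)
            ols_loss = check_loss(y - X.to_numpy() @ ols_beta, q)
            assert fit.objective <= ols_loss + 1e-8

    def test_no_axis_aligned_improvement(self):
        rng = np.random.default_rng(19)
        x = rng.standard_normal(50)
        y = 2.0 - 0.5 * x + rng.standard_normal(50)
        X = design(x)
        for q in (0.25, 0.5, 0.75):
            fit = fit_quantile(y, X, q)
            base = check_loss(y - X.to_numpy() @ fit.params.to_numpy(), q)
            for k in range(2):
                for delta in (1e-4, -1e-4):
                    perturbed = fit.params.to_numpy().copy()
                    perturbed[k] += delta
                    assert check_loss(y - X.to_numpy() @ perturbed, q) >= base - 1e-9

    def test_scale_equivariance(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal(40)
        y = 1.0 + 2.0 * x + rng.standard_normal(40)
        f1 = fit_quantile(y, design(x), 0.25)
        f2 = fit_quantile(3.0 * y, design(x), 0.25)
        np.testing.assert_allclose(
            f2.params.to_numpy(), 3.0 * f1.params.to_numpy(), rtol=1e-5, atol=1e-6
        )

    def test_degenerate_outcome_warns_zero_slope(self):
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_quantile(np.full(10, 7.0), design(np.arange(10.0)), 0.5)
        assert fit.params["overall"] == 0.0
        assert fit.params["const"] == 7.0

    def test_small_tail_flagged(self):
        rng = np.random.default_rng(15)
        x = rng.standard_normal(90)
        y = x + rng.standard_normal(90)
        with pytest.warns(UserWarning, match="tail"):
            fit = fit_quantile(y, design(x), 0.95)
        assert fit.small_tail

    def test_invalid_quantile(self):
        with pytest.raises(MgmtPerfError):
            fit_quantile(np.arange(5.0), design(np.arange(5.0)), 1.5)


class TestBootstrap:
    def test_seed_determinism(self):
        rng = np.random.default_rng(16)
        x = rng.standard_normal(60)
        y = 1.0 + x + rng.standard_normal(60)
        X = design(x)
        t1, se1 = bootstrap_quantile_tests(y, X, quantiles=(0.25, 0.75), B=100, seed=5)
        t2, se2 = bootstrap_quantile_tests(y, X, quantiles=(0.25, 0.75), B=100, seed=5)
        assert t1[0].p_value == t2[0].p_value
        assert se1 == se2

    def test_pair_symmetry_and_bounds(self):
        rng = np.random.default_rng(17)
        x = rng.standard_normal(60)
        y = 1.0 + x + rng.standard_normal(60)
        tests, _ = bootstrap_quantile_tests(
            y, design(x), quantiles=(0.25, 0.5, 0.75), B=100, seed=1
        )
        assert len(tests) == 3  # lower triangle of pairs
        for t in tests:
            assert 0.0 <= t.p_value <= 1.0
            assert t.bootstrap_se >= 0.0

    def test_percentile_method(self):
        rng = np.random.default_rng(18)
        x = rng.standard_normal(50)
        y = 1.0 + x + rng.standard_normal(50)
        tests, _ = bootstrap_quantile_tests(
            y, design(x), quantiles=(0.25, 0.75), B=100, seed=2, method="percentile"
        )
        assert 0.0 <= tests[0].p_value <= 1.0

    def test_minimum_reps_enforced(self):
        with pytest.raises(MgmtPerfError):
            bootstrap_quantile_tests(
                np.arange(20.0), design(np.arange(20.0)), quantiles=(0.5,), B=50
            )

    def test_power_under_location_scale(self):
        # With residual SD increasing in x, the q25 and q75 slopes truly
        # differ; the paired test should reject well above the 5% level.
        rejections = 0
        n_data = 30
        for seed in range(n_data):
            rng = np.random.default_rng(1000 + seed)
            x = rng.standard_normal(90)
            y = 10.0 + 2.0 * x + (1.0 + 0.6 * np.clip(x, -1.5, None)) * rng.standard_normal(90)
            tests, _ = bootstrap_quantile_tests(
                y, design(x), quantiles=(0.25, 0.75), B=100, seed=seed
            )
            if tests[0].p_value < 0.05:
                rejections += 1
        assert rejections / n_data > 0.5


class TestQuantileTable:
    def test_report_structure(self, adjusted_frame, panel):
        reports = quantile_table(
            adjusted_frame,
            panel,
            quantiles=(0.25, 0.5, 0.75, 0.95),
            B=100,
            seed=3,
            outcomes=["n_hts", "uc_hts"],
        )
        frame = reports["n_hts"].to_frame()
        assert len(frame) == 4  # one row per quantile
        assert set(["p_vs_q25", "p_vs_q50", "p_vs_q75"]) <= set(frame.columns)
        # Lower-triangular p-value block: q25 row has no comparisons.
        q25_row = frame[frame["q"] == 0.25].iloc[0]
        assert np.isnan(q25_row["p_vs_q50"])
        q95_row = frame[frame["q"] == 0.95].iloc[0]
        assert not np.isnan(q95_row["p_vs_q25"])
        assert (frame["se_boot"] >= 0).all()
        assert reports["n_hts"].nobs == 90
        assert reports["uc_hts"].nobs == 90

    def test_sign_consistency_under_strong_effect(self):
        # Constant positive true slope: all four quantile estimates positive
        # in nearly every replicate when noise is small.
        hits, n_rep = 0, 20
        for seed in range(n_rep):
            bundle = generate_cbo_panel(
                GeneratorConfig(
                    seed=seed,
                    noise_sd={"condoms_per_reached": 20.0},
                    missing_art_rows=0,
                )
            )
            z = bundle.panel["cbo_id"].map(bundle.truth["z"]).to_numpy()
            y = bundle.panel["condoms_per_reached"].to_numpy()
            X = design(z)
            slopes = [
                fit_quantile(y, X, q).params["overall"] for q in (0.25, 0.5, 0.75, 0.95)
            ]
            if all(s > 0 for s in slopes):
                hits += 1
        assert hits >= 0.95 * n_rep

    def test_missing_outcome_errors(self, adjusted_frame, panel):
        with pytest.raises(MgmtPerfError, match="missing"):
            quantile_table(adjusted_frame, panel, B=100, outcomes=["not_a_column"])


def test_true_quantile_slope_analytic():
    cfg = GeneratorConfig(seed=0, quantile_scale=0.3)
    bundle = generate_cbo_panel(cfg)
    from scipy.stats import norm

    t = bundle.truth
    for q in (0.25, 0.5, 0.75, 0.95):
        expected = t["beta_true"]["uc_art"] + t["noise_sd"]["uc_art"] * 0.3 * norm.ppf(q)
        assert true_quantile_slope(t, "uc_art", q) == pytest.approx(expected)
    assert true_quantile_slope(t, "n_hts", 0.9) == t["beta_true"]["n_hts"]
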