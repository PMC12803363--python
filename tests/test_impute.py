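import math

import numpy as np
import pandas as pd
import pytest

from trajimpute.impute import (
    ImputationProblem,
    LocalModelFit,
    build_covariate_design,
    fit_local_model,
    impute_cell,
    mask_and_recover,
    run_multiple_imputation,
    sweep,
    trace_max_changes,
    trace_mean_changes,
)
from trajimpute.simulate import SimulationConfig, cohort_tables, simulate_cohort
from trajimpute.preprocess import run_preprocess

from conftest import make_covariates


def aligned_frame(values: np.ndarray) -> pd.DataFrame:
    """Long frame from a wide (n_patients, T) array with NaN for missing."""
    n, T = values.shape
    rows = [
        {"patient_id": f"p{i:03d}", "t_index": t, "value": values[i, t]}
        for i in range(n)
        for t in range(T)
    ]
    return pd.DataFrame(rows)


class TestCovariateDesign:
    def test_one_hot_reference_levels(self):
        cov = pd.DataFrame(
            {
                "patient_id": ["a", "b"],
                "age_at_dx": [50.0, 60.0],
                "bmi": [25.0, 30.0],
                "sex": ["F", "M"],
                "first_line_treatment": ["imatinib", "nilotinib"],
            }
        )
        x, names = build_covariate_design(cov, ["a", "b"])
        assert names == [
            "age_at_dx", "bmi", "sex_M",
            "first_line_treatment_dasatinib", "first_line_treatment_nilotinib",
        ]
        np.testing.assert_allclose(x[0], [50.0, 25.0, 0, 0, 0])
        np.testing.assert_allclose(x[1], [60.0, 30.0, 1, 0, 1])

    def test_missing_bmi_indicator(self):
        cov = pd.DataFrame(
            {
                "patient_id": ["a", "b"],
                "age_at_dx": [50.0, 60.0],
                "bmi": [25.0, np.nan],
                "sex": ["F", "F"],
                "first_line_treatment": ["imatinib", "imatinib"],
            }
        )
        x, names = build_covariate_design(cov, ["a", "b"])
        assert "bmi_missing" in names
        j = names.index("bmi")
        assert x[1, j] == pytest.approx(25.0)  # cohort mean fill

    def test_unknown_level_rejected(self):
        cov = pd.DataFrame(
            {
                "patient_id": ["a"],
                "age_at_dx": [50.0],
                "bmi": [25.0],
                "sex": ["X"],
                "first_line_treatment": ["imatinib"],
            }
        )
        with pytest.raises(ValueError, match="sex"):
            build_covariate_design(cov, ["a"])


class TestFitLocalModel:
    def test_exact_linear_data(self):
        rng = np.random.default_rng(0)
        n = 60
        z = rng.normal(size=(n, 4))
        x = rng.normal(size=(n, 2))
        y = 1.0 + 0.5 * z[:, 2]  # intercept + lead1 only
        fit = fit_local_model(y, z, x, t_index=3)
        assert not fit.degenerate
        assert fit.intercept == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(fit.beta, [0, 0, 0.5, 0], atol=1e-8)
        np.testing.assert_allclose(fit.gamma, [0, 0], atol=1e-8)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-7)

    def test_underdetermined_flagged_degenerate(self):
        rng = np.random.default_rng(1)
        fit = fit_local_model(rng.normal(size=4), rng.normal(size=(4, 4)), rng.normal(size=(4, 2)))
        assert fit.degenerate

    def test_collinear_flagged_degenerate(self):
        rng = np.random.default_rng(2)
        z = np.tile(rng.normal(size=(20, 1)), (1, 4))  # identical columns
        fit = fit_local_model(rng.normal(size=20), z, rng.normal(size=(20, 1)))
        assert fit.degenerate

    def test_residual_sd_denominator(self):
        rng = np.random.default_rng(3)
        n = 50
        z = rng.normal(size=(n, 4))
        x = np.zeros((n, 0))
        y = rng.normal(size=n)
        fit = fit_local_model(y, z, x)
        design = np.column_stack([np.ones(n), z])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        expect = math.sqrt(resid @ resid / (n - 5))
        assert fit.residual_sd == pytest.approx(expect)

    def test_parameter_recovery_smoke(self):
        # full 100-replicate version lives in the acceptance suite
        rng = np.random.default_rng(4)
        alpha, beta, gamma, sigma = -2.0, np.array([0.1, 0.6, 0.5, 0.05]), np.array([0.02]), 0.8
        n = 500
        z = rng.normal(size=(n, 4))
        x = rng.normal(size=(n, 1))
        y = alpha + z @ beta + x @ gamma + rng.normal(0, sigma, n)
        fit = fit_local_model(y, z, x)
        truth = np.concatenate([[alpha], beta, gamma])
        assert np.all(np.abs(fit.coef - truth) < 4 * fit.se)


class TestImputeCell:
    def _fit(self, sigma):
        return LocalModelFit(
            t_index=1,
            intercept=2.0,
            beta=np.array([0.1, 0.4, 0.3, 0.05]),
            gamma=np.array([0.01]),
            residual_sd=sigma,
            n_fit=100,
            se=np.zeros(6),
        )

    def test_deterministic_limit(self):
        val = impute_cell(self._fit(0.0), np.zeros(4), np.zeros(1), np.random.default_rng(0))
        assert val == pytest.approx(2.0)

    def test_fixed_seed_repeatable(self):
        z, x = np.ones(4), np.ones(1)
        a = impute_cell(self._fit(1.0), z, x, np.random.default_rng(42))
        b = impute_cell(self._fit(1.0), z, x, np.random.default_rng(42))
        assert a == b

    def test_noise_moments(self):
        fit = self._fit(0.7)
        z = np.array([0.2, -0.1, 0.3, 0.0])
        x = np.array([1.5])
        mu = fit.linear_predictor(z[None], x[None])[0]
        rng = np.random.default_rng(7)
        draws = np.array([impute_cell(fit, z, x, rng) for _ in range(10_000)])
        assert abs(draws.mean() - mu) < 4 * 0.7 / 100
        assert abs(draws.std() - 0.7) / 0.7 < 0.05

    def test_degenerate_fit_rejected(self):
        bad = LocalModelFit(0, math.nan, np.full(4, np.nan), np.zeros(0),
                            math.nan, 2, np.full(5, np.nan), degenerate=True)
        with pytest.raises(ValueError):
            impute_cell(bad, np.zeros(4), np.zeros(0), np.random.default_rng(0))


def synthetic_aligned(seed=11, n=60, followup=1620):
    cfg = SimulationConfig(n_patients=n, followup_days=followup, seed=seed)
    tables = cohort_tables(simulate_cohort(cfg))
    aligned, _ = run_preprocess(tables["measurements"], tables["treatment"])
    return aligned, tables["covariates"]


class TestSweep:
    def test_complete_grid_unchanged(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(30, 6))
        problem = ImputationProblem(aligned_frame(vals), make_covariates([f"p{i:03d}" for i in range(30)]))
        state = problem.initial_state()
        out = sweep(problem, state, np.random.default_rng(1))
        np.testing.assert_array_equal(out, vals)

    def test_observed_cells_never_modified(self, small_aligned, small_tables):
        problem = ImputationProblem(small_aligned, small_tables["covariates"])
        state = problem.initial_state()
        out = sweep(problem, state, np.random.default_rng(2))
        np.testing.assert_array_equal(
            out[problem.observed], problem.values[problem.observed]
        )

    def test_masked_cell_mae_below_marginal_sd(self):
        aligned, cov = synthetic_aligned(seed=21, n=100)
        problem = ImputationProblem(aligned, cov)
        state = problem.initial_state()
        out = sweep(problem, state, np.random.default_rng(3))
        # one refinement sweep should already beat the marginal spread
        truth_sd = np.nanstd(problem.values[problem.observed])
        filled = out[~problem.observed & problem.in_window]
        assert np.isfinite(filled).all()
        assert np.abs(filled - np.nanmean(problem.values[problem.observed])).mean() < 2 * truth_sd


class TestRunMultipleImputation:
    def test_observed_preserved_and_complete(self, small_aligned, small_tables):
        result = run_multiple_imputation(
            small_aligned, small_tables["covariates"], burnin=5, m=4, seed=0
        )
        prob = result.problem
        for ds in result.datasets:
            np.testing.assert_array_equal(ds[prob.observed], prob.values[prob.observed])
            assert np.isfinite(ds[prob.in_window]).all()

    def test_deterministic_under_seed(self, small_aligned, small_tables):
        a = run_multiple_imputation(small_aligned, small_tables["covariates"], burnin=3, m=2, seed=5)
        b = run_multiple_imputation(small_aligned, small_tables["covariates"], burnin=3, m=2, seed=5)
        for da, db in zip(a.datasets, b.datasets):
            np.testing.assert_array_equal(da, db)

    def test_imputations_differ_when_noise_positive(self, small_aligned, small_tables):
        result = run_multiple_imputation(
            small_aligned, small_tables["covariates"], burnin=3, m=3, seed=1
        )
        prob = result.problem
        imp_mask = ~prob.observed & prob.in_window
        stack = np.stack([ds[imp_mask] for ds in result.datasets])
        assert np.ptp(stack, axis=0).max() > 0

    def test_between_imputation_spread_grows_with_noise(self):
        def spread(ar_sd, noise_sd):
            cfg = SimulationConfig(n_patients=80, followup_days=1260, seed=33,
                                   ar_sd=ar_sd, noise_sd=noise_sd)
            tables = cohort_tables(simulate_cohort(cfg))
            aligned, _ = run_preprocess(tables["measurements"], tables["treatment"])
            res = run_multiple_imputation(aligned, tables["covariates"], burnin=5, m=5, seed=33)
            prob = res.problem
            imp_mask = ~prob.observed & prob.in_window
            stack = np.stack([ds[imp_mask] for ds in res.datasets])
            return float(stack.std(axis=0, ddof=1).mean())

        assert spread(0.9, 0.6) > spread(0.1, 0.05)

    def test_traces_recorded(self, small_aligned, small_tables):
        res = run_multiple_imputation(small_aligned, small_tables["covariates"], burnin=4, m=1, seed=2)
        assert set(res.traces.columns) == {"iteration", "t_index", "coefficient", "estimate", "se"}
        assert res.traces["iteration"].max() == 3
        assert len(trace_max_changes(res.traces)) == 3
        assert len(trace_mean_changes(res.traces)) == 3

    def test_independent_chains_option(self, small_aligned, small_tables):
        res = run_multiple_imputation(
            small_aligned, small_tables["covariates"], burnin=2, m=2, seed=3,
            independent_chains=True,
        )
        assert res.m == 2
        prob = res.problem
        for ds in res.datasets:
            np.testing.assert_array_equal(ds[prob.observed], prob.values[prob.observed])

    def test_pmm_draws_from_observed_support(self, small_aligned, small_tables):
        res = run_multiple_imputation(
            small_aligned, small_tables["covariates"], burnin=3, m=2, seed=4, pmm=True
        )
        prob = res.problem
        for ds in res.datasets:
            for t in range(ds.shape[1]):
                obs_vals = set(prob.values[prob.observed[:, t], t])
                fill = ds[~prob.observed[:, t] & prob.in_window[:, t], t]
                assert all(v in obs_vals for v in fill)

    def test_long_format_roundtrip(self, small_aligned, small_tables):
        res = run_multiple_imputation(small_aligned, small_tables["covariates"], burnin=2, m=2, seed=6)
        frame = res.to_frame()
        assert frame["value"].notna().all()
        assert set(frame["imputation_id"]) == {0, 1}
        observed_rows = frame[~frame["was_imputed"]]
        pivots = observed_rows.pivot_table(
            index=["patient_id", "t_index"], columns="imputation_id", values="value"
        )
        np.testing.assert_allclose(pivots[0], pivots[1])


class TestLeadLagDominance:
    def test_adjacent_coefficients_dominate(self):
        aligned, cov = synthetic_aligned(seed=44, n=150, followup=1800)
        res = run_multiple_imputation(aligned, cov, burnin=8, m=1, seed=44)
        last = res.traces[res.traces["iteration"] == res.traces["iteration"].max()]
        mags = last.groupby("coefficient")["estimate"].apply(lambda s: s.abs().mean())
        assert mags["lag1"] > mags["lag2"]
        assert mags["lead1"] > mags["lead2"]


class TestMaskAndRecover:
    def test_zero_fraction_empty_report(self, small_tables):
        cohort_grid = small_tables["true_grid"]
        rep = mask_and_recover(cohort_grid, small_tables["covariates"], 0.0, seed=0)
        assert rep.n_masked == 0 and math.isnan(rep.rmse_pooled)

    def test_invalid_fraction_rejected(self, small_tables):
        with pytest.raises(ValueError):
            mask_and_recover(small_tables["true_grid"], small_tables["covariates"], 1.5, seed=0)

    def test_near_noiseless_recovery(self):
        # straight-line trajectories are exactly linear in (lag1, lead1),
        # so recovery error should shrink to the tiny residual noise level
        rng = np.random.default_rng(8)
        n, T = 80, 12
        a = rng.normal(-3, 2, size=n)
        b = rng.normal(-0.3, 0.1, size=n)
        vals = a[:, None] + b[:, None] * np.arange(T) + rng.normal(0, 0.01, (n, T))
        grid = aligned_frame(vals)[["patient_id", "t_index", "value"]]
        cov = make_covariates([f"p{i:03d}" for i in range(n)])
        rep = mask_and_recover(grid, cov, 0.1, seed=8, burnin=8, m=5)
        assert rep.rmse_pooled < 0.05

    def test_recovery_beats_column_mean(self, small_tables):
        rep = mask_and_recover(
            small_tables["true_grid"], small_tables["covariates"], 0.1,
            seed=1, burnin=10, m=5,
        )
        assert rep.n_masked > 0
        assert rep.rmse_pooled < rep.rmse_column_mean
        assert 0.0 <= rep.coverage <= 1.0
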