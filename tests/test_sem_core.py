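"""Estimation core: discrepancy, fitting, robust statistics, indices."""

import numpy as np
import pytest
from scipy import stats

import watershed_sem as ws
from watershed_sem.estimator import (
    SampleMoments,
    _independence_fit,
    fit_indices,
    fit_model,
    implied_covariance,
    ml_discrepancy,
    modification_indices,
    compare_nested,
)
from watershed_sem.model import build_parameter_table, parse_model_syntax

from oracles import path_tracing_sigma, simplex_ml_fit


def _valued_table(text, values):
    table = build_parameter_table(parse_model_syntax(text), check_identification=False)
    table.set_values(values)
    return table


class TestImpliedCovariance:
    def test_diagonal_model_gives_identity(self):
        table = _valued_table(
            "a ~~ a\nb ~~ b", {("a", "variance", "a"): 1.0, ("b", "variance", "b"): 1.0}
        )
        assert np.allclose(implied_covariance(table), np.eye(2))

    def test_one_factor_hand_matrix(self):
        values = {
            ("F", "loading", "x1"): 1.0,
            ("F", "loading", "x2"): 0.8,
            ("F", "variance", "F"): 1.0,
            ("x1", "variance", "x1"): 0.5,
            ("x2", "variance", "x2"): 0.5,
        }
        table = _valued_table("F =~ 1*x1 + 0.8*x2", values)
        assert np.allclose(implied_covariance(table), [[1.5, 0.8], [0.8, 1.14]])

    def test_chained_unit_paths_transmit_unit_covariance(self):
        values = {
            ("m", "regression", "x"): 1.0,
            ("y", "regression", "m"): 1.0,
            ("x", "variance", "x"): 1.0,
            ("m", "variance", "m"): 1.0,
            ("y", "variance", "y"): 1.0,
        }
        table = _valued_table("m ~ x\ny ~ m", values)
        sigma = implied_covariance(table)
        names = table.spec.observed_names
        assert sigma[names.index("x"), names.index("y")] == pytest.approx(1.0)

    def test_matches_path_tracing_oracle(self, truth):
        sigma = path_tracing_sigma(truth.table, truth.values)
        assert np.allclose(sigma, truth.implied, atol=1e-12)


class TestMLDiscrepancy:
    def test_zero_iff_equal(self):
        S = np.array([[2.0, 0.3], [0.3, 1.0]])
        assert ml_discrepancy(S, S) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert ml_discrepancy(S, np.eye(2)) == pytest.approx(-np.log(0.75), abs=1e-12)

    def test_decreases_along_line_toward_S(self):
        rng = np.random.default_rng(5)
        A = rng.standard_normal((4, 4))
        S = A @ A.T + 4 * np.eye(4)
        B = rng.standard_normal((4, 4))
        Sigma0 = S + 0.5 * (B @ B.T) / 4
        ts = np.linspace(0.0, 1.0, 12)
        vals = [ml_discrepancy(S, Sigma0 + t * (S - Sigma0)) for t in ts]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_rejects_non_positive_definite(self):
        with pytest.raises(ValueError, match="positive definite"):
            ml_discrepancy(np.array([[1.0, 2.0], [2.0, 1.0]]), np.eye(2))


class TestFitModel:
    def test_self_consistency_on_implied_covariance(self, truth, population_moments):
        fit = ws.fit_model(truth.spec, population_moments, robust=False)
        assert fit.converged
        assert fit.T_ml == pytest.approx(0.0, abs=1e-6)
        vals = fit.table.values()
        for key, v in truth.free_parameter_truth().items():
            assert vals[key] == pytest.approx(v, abs=1e-4)

    def test_just_identified_closed_form(self):
        # 1-factor, 3-indicator model: analytic solution from the covariances
        S = np.array(
            [
                [1.20, 0.48, 0.42],
                [0.48, 0.98, 0.36],
                [0.42, 0.36, 1.05],
            ]
        )
        moments = SampleMoments(S=S, names=["x1", "x2", "x3"], n=200)
        fit = fit_model("F =~ x1 + x2 + x3", moments, robust=False)
        phi = S[0, 1] * S[0, 2] / S[1, 2]
        lam2, lam3 = S[1, 2] / S[0, 2], S[1, 2] / S[0, 1]
        vals = fit.table.values()
        assert fit.T_ml == pytest.approx(0.0, abs=1e-7)
        assert vals[("F", "variance", "F")] == pytest.approx(phi, abs=1e-6)
        assert vals[("F", "loading", "x2")] == pytest.approx(lam2, abs=1e-6)
        assert vals[("F", "loading", "x3")] == pytest.approx(lam3, abs=1e-6)
        assert vals[("x1", "variance", "x1")] == pytest.approx(S[0, 0] - phi, abs=1e-6)

    @pytest.mark.parametrize(
        "seed, text",
        [
            (1, "F =~ x1 + x2 + x3 + x4"),
            (2, "y ~ x1 + x2"),
            (3, "F =~ x1 + x2 + x3\ny ~ F"),
            (4, "F =~ x1 + x2 + x3 + x4\nF ~ z"),
            (5, "y ~ x1\nz ~ y"),
        ],
    )
    def test_agrees_with_simplex_likelihood_oracle(self, seed, text):
        """Quasi-Newton estimates match derivative-free raw-likelihood fits on
        data sampled from structured populations."""
        rng = np.random.default_rng(seed)
        spec = parse_model_syntax(text)
        table = build_parameter_table(spec)
        pop = {}
        for row in table.rows:
            if row.op == "variance":
                pop[row.key()] = 1.0
            elif row.fixed is not None:
                pop[row.key()] = row.fixed
            elif row.op == "covariance":
                pop[row.key()] = 0.3
            else:
                pop[row.key()] = 0.4 + 0.1 * (row.free_index % 3)
        sigma_pop = path_tracing_sigma(table, pop)
        p = sigma_pop.shape[0]
        X = rng.standard_normal((300, p)) @ np.linalg.cholesky(sigma_pop).T
        S = np.cov(X, rowvar=False, ddof=1)
        moments = SampleMoments(S=S, names=spec.observed_names, n=300)
        fit = fit_model(spec, moments, robust=False, compute_baseline=False)
        theta_ref, F_ref = simplex_ml_fit(spec, S, 300, x0=fit.theta + 0.05)
        assert fit.F_min <= F_ref + 1e-8
        assert np.allclose(fit.theta, theta_ref, atol=1e-4)

    def test_non_positive_definite_refused_then_ridged(self):
        S = np.array([[1.0, 1.0], [1.0, 1.0]])
        moments = SampleMoments(S=S, names=["a", "b"], n=50)
        with pytest.raises(ValueError, match="positive definite"):
            fit_model("a ~~ b", moments, robust=False)
        with pytest.warns(UserWarning, match="ridge"):
            fit = fit_model("a ~~ b", moments, robust=False, ridge=True)
        assert fit.T_ml == pytest.approx(0.0, abs=1e-4)  # saturated after ridging

    def test_nested_constraint_monotonicity(self, moments555):
        """T of any constrained variant exceeds T of the free model."""
        full = ws.fit_model(ws.build_mimic(), moments555, robust=False)
        for kind in ("zero_paths", "equal_paths", "source_specific"):
            variant = ws.make_variant(ws.build_mimic(), kind, block="ps_fi")
            restricted = ws.fit_model(variant, moments555, robust=False)
            assert restricted.T_ml >= full.T_ml - 1e-6


class TestFitIndices:
    def test_t_equal_df_gives_zero_rmsea(self):
        idx = fit_indices(T=10.0, df=10, n=200, T_base=500.0, df_base=45)
        assert idx.rmsea == 0.0
        assert idx.rmsea_ci_low == 0.0
        assert idx.cfi == 1.0

    def test_perfect_fit_srmr_zero(self):
        S = np.array([[1.0, 0.4], [0.4, 1.0]])
        idx = fit_indices(T=0.0, df=1, n=100, T_base=50.0, df_base=1, S=S, Sigma=S)
        assert idx.srmr == pytest.approx(0.0)

    def test_rmsea_ci_brackets_point_estimate(self, watershed_fit):
        idx = watershed_fit.indices
        assert idx.rmsea_ci_low <= idx.rmsea <= idx.rmsea_ci_high

    def test_rmsea_ci_inverts_noncentral_cdf(self):
        T, df, n = 103.2, 60, 555
        idx = fit_indices(T=T, df=df, n=n, T_base=2000.0, df_base=190)
        nc_low = idx.rmsea_ci_low**2 * df * (n - 1)
        nc_high = idx.rmsea_ci_high**2 * df * (n - 1)
        assert stats.ncx2.cdf(T, df, nc_low) == pytest.approx(0.95, abs=1e-6)
        assert stats.ncx2.cdf(T, df, nc_high) == pytest.approx(0.05, abs=1e-6)

    def test_df_zero_reported_not_applicable(self):
        idx = fit_indices(T=0.0, df=0, n=100, T_base=10.0, df_base=3)
        assert np.isnan(idx.rmsea)

    def test_independence_baseline_is_analytic(self, moments555):
        fit = ws.fit_model(ws.build_measurement_model(list(ws.DEFAULT_CONFIG.fi_indicators)),
                           moments555, robust=False)
        p = 4
        sub = moments555.select(list(ws.DEFAULT_CONFIG.fi_indicators))
        T_base, df_base = _independence_fit(sub.S, sub.n)
        assert df_base == p * (p - 1) // 2
        assert fit.baseline_T == pytest.approx(T_base)


class TestRobustStatistics:
    def test_scaling_factor_near_one_under_normality(self, truth):
        data = ws.simulate_dataset(truth, ws.SimulationConfig(n=20000, seed=31))
        fit = ws.fit_model(ws.build_mimic(), ws.SampleMoments.from_data(data))
        assert fit.scaling_factor == pytest.approx(1.0, abs=0.05)
        # robust and expected-information standard errors coincide
        assert np.allclose(fit.se_robust, fit.se_expected, rtol=0.1)

    def test_df_unchanged_and_scaled_relation(self, watershed_fit):
        assert watershed_fit.df == 60
        assert watershed_fit.T_scaled == pytest.approx(
            watershed_fit.T_ml / watershed_fit.scaling_factor
        )
        assert watershed_fit.scaling_factor > 0

    def test_scaled_statistic_closer_to_nominal_under_nonnormality(self, truth):
        """Under skewed/kurtotic data the scaled test's rejection rate beats
        the plain test's (the reason the robust statistic is reported)."""
        spec = ws.build_measurement_model(list(ws.DEFAULT_CONFIG.fi_indicators))
        cfg = ws.SimulationConfig(
            n=400, seed=77, replicates=120, distribution="nonnormal",
            skew=1.8, excess_kurtosis=6.0,
        )
        table = ws.type1_calibration(truth, cfg, model=spec, robust=True)
        rate = dict(zip(table.statistic, table.rejection_rate))
        assert abs(rate["satorra_bentler"] - 0.05) < abs(rate["ml"] - 0.05)


class TestModificationIndices:
    def test_saturated_model_has_no_candidates(self):
        rng = np.random.default_rng(8)
        A = rng.standard_normal((3, 6))
        S = A @ A.T / 6 + np.eye(3)
        names = ["a", "b", "c"]
        text = "\n".join(f"{x} ~~ {y}" for i, x in enumerate(names) for y in names[i:])
        fit = fit_model(text, SampleMoments(S=S, names=names, n=100), robust=False)
        assert modification_indices(fit) == []

    def test_planted_omission_found_and_matches_refit(self, truth):
        """The MI of an omitted path tops the scan and approximates the
        chi-square drop from actually freeing it."""
        null = ws.default_truth(effect_profile="null-hierarchy")
        data = ws.simulate_dataset(null, ws.SimulationConfig(n=3000, seed=13))
        moments = ws.SampleMoments.from_data(data)
        fit = ws.fit_model(ws.build_full_watershed(), moments, robust=False)
        mis = modification_indices(fit)
        regressions = [m for m in mis if m.op == "regression" and m.lhs == "FI"]
        assert regressions[0].rhs == "FMin"
        aug = ws.make_variant(ws.build_full_watershed(), "plus_direct_path", source="FMin")
        refit = ws.fit_model(aug, moments, robust=False)
        delta = fit.T_ml - refit.T_ml
        assert regressions[0].mi == pytest.approx(delta, rel=0.25)


class TestComparisonsAndSummaries:
    def test_identical_models_compare_to_zero(self, moments555):
        f1 = ws.fit_model(ws.build_mimic(), moments555, robust=False)
        f2 = ws.fit_model(ws.build_mimic(), moments555, robust=False)
        cmp = compare_nested(f1, f2)
        assert cmp.delta_df == 0 and cmp.delta_T == pytest.approx(0.0, abs=1e-8)

    def test_non_nested_rejected(self, moments555):
        water = ws.fit_model(ws.build_full_watershed(), moments555, robust=False)
        inv = ws.fit_model(ws.build_inverted_watershed(), moments555, robust=False)
        with pytest.raises(ValueError, match="not nested"):
            compare_nested(inv, water)

    def test_scaled_difference_statistic(self, moments555):
        full = ws.fit_model(ws.build_mimic(), moments555)
        restricted = ws.fit_model(
            ws.make_variant(ws.build_mimic(), "zero_paths", block="ps_fi"), moments555
        )
        cmp = compare_nested(restricted, full)
        assert cmp.delta_df == 6
        assert cmp.delta_T_scaled is not None and cmp.delta_T_scaled > 0

    def test_aic_saturated_is_twice_moment_count(self):
        rng = np.random.default_rng(9)
        A = rng.standard_normal((3, 9))
        S = A @ A.T / 9 + np.eye(3)
        names = ["a", "b", "c"]
        text = "\n".join(f"{x} ~~ {y}" for i, x in enumerate(names) for y in names[i:])
        fit = fit_model(text, SampleMoments(S=S, names=names, n=100), robust=False)
        assert fit.aic == pytest.approx(2 * 6)

    def test_r_squared_single_predictor_closed_form(self):
        S = np.array([[1.0, 0.6], [0.6, 2.0]])
        moments = SampleMoments(S=S, names=["x", "y"], n=500)
        fit = fit_model("y ~ x", moments, robust=False)
        beta = 0.6 / 1.0
        expected = beta**2 * 1.0 / 2.0
        assert fit.r2["y"] == pytest.approx(expected, abs=1e-6)

    def test_r_squared_zero_without_predictors(self, population_moments):
        fit = ws.fit_model(
            ws.make_variant(ws.build_mimic(), "zero_paths", block="ps_fi"),
            population_moments.select(
                list(ws.DEFAULT_CONFIG.ps_variables) + list(ws.DEFAULT_CONFIG.fi_indicators)
            ),
            robust=False,
        )
        assert fit.r2["FI"] == pytest.approx(0.0, abs=1e-8)


class TestSklearnInterface:
    def test_estimator_fit_and_attributes(self, data555):
        est = ws.StructuralEquationModel(ws.build_mimic(), robust=True)
        est.fit(data555)
        assert est.df_ == 20
        assert est.converged_
        assert est.stat_scaled_ is not None
        assert 0 <= est.r2_["FI"] <= 1
        assert est.parameter_table_.shape[0] == est.result_.table.to_frame().shape[0]

    def test_get_params_round_trip(self):
        est = ws.StructuralEquationModel("F =~ a + b + c", max_iter=123)
        params = est.get_params()
        clone = ws.StructuralEquationModel(**params)
        assert clone.max_iter == 123

    def test_fit_moments_matches_fit(self, data555):
        est1 = ws.StructuralEquationModel(ws.build_mimic(), robust=False).fit(data555)
        mom = ws.SampleMoments.from_data(data555)
        est2 = ws.StructuralEquationModel(ws.build_mimic()).fit_moments(
            mom.S, mom.n, names=mom.names
        )
        assert est1.stat_ == pytest.approx(est2.stat_, abs=1e-8)
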