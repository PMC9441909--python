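"""One-factor categorical CFA: DWLS estimates, scaled statistic, fit indices."""

import numpy as np
import pytest

from smdsnet.cfa import (
    FactorModelSpec,
    IdentificationError,
    fit_factor_model,
    fit_indices,
    implied_correlations,
    omega_reliability,
    residual_correlations,
    rmsea_from_t,
    rmsea_ci,
)
from smdsnet.polychoric import estimate_summary
from smdsnet.simulate import simulate_onefactor, simulate_residual_dependence


class TestFit:
    def test_recovery_within_ci_single_run(self, onefactor_summary, table_params):
        lam, tau = table_params
        params, fitres, fit = fit_factor_model(onefactor_summary)
        ci = params.loading_ci()
        assert np.mean((ci[:, 0] <= lam) & (lam <= ci[:, 1])) >= 8 / 9
        np.testing.assert_allclose(params.loadings, lam, atol=0.04)
        assert fit.converged

    def test_two_items_unidentified(self):
        m = simulate_onefactor(np.array([0.7, 0.7]), np.zeros(2), 2000, seed=1)
        s = estimate_summary(m.values, [2, 2])
        with pytest.raises(IdentificationError):
            fit_factor_model(s)

    def test_population_exact_input_is_fixed_point(self, population_summary,
                                                   table_params):
        lam, tau = table_params
        params, fitres, fit = fit_factor_model(population_summary)
        np.testing.assert_allclose(params.loadings, lam, atol=1e-5)
        assert fit.t0 < 1e-6
        assert fitres.t_scaled < 1e-4

    def test_item_reordering_permutes_estimates(self, onefactor_data):
        perm = np.array([3, 1, 4, 0, 2, 8, 6, 7, 5])
        s1 = estimate_summary(onefactor_data.values, [2] * 9)
        s2 = estimate_summary(onefactor_data.values[:, perm], [2] * 9)
        p1, _, _ = fit_factor_model(s1)
        p2, _, _ = fit_factor_model(s2)
        np.testing.assert_allclose(p2.loadings, p1.loadings[perm], atol=1e-6)

    def test_dwls_objective_optimal(self, onefactor_summary, table_params):
        """Fitted objective cannot exceed the generating-parameter objective."""
        lam, tau = table_params
        _, _, fit = fit_factor_model(onefactor_summary)
        w = fit.weights
        r0 = fit.stats - np.outer(lam, lam)[np.triu_indices(9, 1)]
        assert fit.t0 <= np.dot(w * r0, r0) + 1e-9


class TestScaledStatistic:
    def test_mean_of_scaled_t_close_to_df(self):
        """Mean-adjustment calibration: E[T] = df under a true model."""
        ts = []
        for rep in range(150):
            m = simulate_onefactor(n=2000, seed=5000 + rep)
            s = estimate_summary(m.values, [2] * 9)
            _, fitres, _ = fit_factor_model(s)
            ts.append(fitres.t_scaled)
        # SE of the mean of ~chi2(27) over 150 reps is ~0.6
        assert np.mean(ts) == pytest.approx(27.0, abs=2.5)

    def test_sf_positive(self, onefactor_summary):
        _, fitres, _ = fit_factor_model(onefactor_summary)
        assert fitres.sf > 0


class TestFitIndices:
    @pytest.mark.parametrize("t, df, expected", [
        (505.36, 27, 0.036),
        (42.33, 17, 0.011),
        (2636.71, 347, 0.022),
    ])
    def test_rmsea_reproduces_printed_values(self, t, df, expected):
        assert round(rmsea_from_t(t, df, 13377), 3) == expected

    def test_saturated_limit(self):
        res = fit_indices(20.0, 27, 1000, 500.0, 36, np.zeros(3))
        assert res.rmsea == 0.0
        assert res.cfi == 1.0

    def test_df_zero_reported_undefined(self):
        res = fit_indices(0.0, 0, 1000, 500.0, 36, np.zeros(3))
        assert np.isnan(res.rmsea)

    def test_rmsea_ci_brackets_point_estimate(self):
        lo, hi = rmsea_ci(505.36, 27, 13377)
        point = rmsea_from_t(505.36, 27, 13377)
        assert lo < point < hi
        assert (round(lo, 3), round(hi, 3)) == (0.034, 0.039)


class TestImpliedAndResiduals:
    def test_one_factor_products(self):
        rho = implied_correlations([0.75, 0.81, 0.5])
        assert rho[0, 1] == pytest.approx(0.6075)
        np.testing.assert_allclose(np.diag(rho), 1.0)

    def test_zero_loadings_identity(self):
        np.testing.assert_array_equal(implied_correlations(np.zeros(4)),
                                      np.eye(4))

    def test_orthogonal_factors_zero_cross_block(self):
        rho = implied_correlations([0.7, 0.7, 0.6, 0.6],
                                   psi=np.eye(2),
                                   item_factor=np.array([0, 0, 1, 1]))
        assert rho[0, 2] == 0.0 and rho[1, 3] == 0.0
        assert rho[0, 1] == pytest.approx(0.49)

    def test_exact_fit_zero_residuals(self):
        rho = implied_correlations([0.7, 0.6, 0.5])
        np.testing.assert_array_equal(residual_correlations(rho, rho),
                                      np.zeros((3, 3)))

    def test_injected_edge_dominates_residuals(self, table_params):
        lam, tau = table_params
        om = np.zeros((9, 9))
        om[5, 8] = om[8, 5] = 0.12
        m = simulate_residual_dependence(lam, tau, om, 50_000, seed=21)
        s = estimate_summary(m.values, [2] * 9)
        params, _, _ = fit_factor_model(s)
        res = residual_correlations(s.rho, implied_correlations(params.loadings))
        assert (abs(res[5, 8]) == np.max(np.abs(res)))

    def test_wellspecified_largescale_residuals_small(self):
        m = simulate_onefactor(n=100_000, seed=22)
        s = estimate_summary(m.values, [2] * 9)
        params, _, _ = fit_factor_model(s)
        res = residual_correlations(s.rho, implied_correlations(params.loadings))
        assert np.max(np.abs(res)) < 0.02


class TestOmega:
    def test_latent_closed_form(self):
        r = omega_reliability(np.full(9, 0.75))
        assert r.omega_latent == pytest.approx(45.5625 / 49.5, abs=1e-12)

    def test_boundary_cases(self):
        assert omega_reliability(np.zeros(5)).omega_latent == 0.0
        assert omega_reliability(np.full(5, 1.0 - 1e-12)).omega_latent == \
            pytest.approx(1.0, abs=1e-6)

    def test_sumscore_omega_below_latent_for_binary(self, table_params):
        lam, tau = table_params
        r = omega_reliability(lam, [np.array([t]) for t in tau], "both")
        assert 0.70 < r.omega_sumscore < r.omega_latent < 0.95
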