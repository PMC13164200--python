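import numpy as np
import pytest
from scipy.stats import multivariate_normal

from aaaforecast import (
    AneurysmGrowthModel,
    FitRegime,
    Layer,
    Response,
    ResponseMatrix,
    fit_lme,
    neg_log_likelihood,
    predict_nodes,
    simulate_response_matrix,
)
from aaaforecast.exceptions import RegimeError
from aaaforecast.growth_lme import VARIANCE_FLOOR, NodeGrowthLME, _profile


def make_Y(values, times):
    return ResponseMatrix(values=np.asarray(values, float),
                          times=np.asarray(times, float),
                          response=Response.RADIUS, layer=Layer.OUTER_WALL)


class TestFitLME:
    def test_identical_lines_zero_noise(self):
        t = np.array([0.0, 300.0, 700.0, 1100.0])
        y = 2.0 + 0.001 * t
        Y = make_Y(np.tile(y, (40, 1)), t)
        fit = fit_lme(Y)
        assert fit.alpha == pytest.approx(2.0, abs=1e-8)
        assert fit.beta == pytest.approx(0.001, abs=1e-8)
        for v in (fit.sigma0_sq, fit.sigma1_sq, fit.sigma_eps_sq):
            assert v <= 10 * VARIANCE_FLOOR
        assert np.abs(fit.b0).max() < 1e-8
        assert np.abs(fit.b1).max() < 1e-8
        np.testing.assert_allclose(fit.fittedvalues(), Y.values, atol=1e-8)

    def test_recovers_intercept_heterogeneity(self):
        # nodes share the slope exactly; intercepts deviate with known spread
        rng = np.random.default_rng(123)
        t = np.array([0.0, 400.0, 800.0, 1200.0])
        G = 1000
        delta = rng.normal(0.0, 0.3, size=G)
        Y = make_Y((2.0 + delta)[:, None] + 0.001 * t[None, :], t)
        fit = fit_lme(Y)
        assert fit.alpha == pytest.approx(2.0, abs=2 * 0.3 / np.sqrt(G) * 2)
        assert fit.sigma0_sq == pytest.approx(delta.var(), rel=0.25)
        assert fit.sigma1_sq <= 1e-9
        assert fit.sigma_eps_sq <= 1e-6 * 0.3**2

    def test_parameter_recovery_from_generating_model(self):
        rng = np.random.default_rng(2024)
        t = np.array([0.0, 400.0, 800.0, 1200.0])
        Y, truth = simulate_response_matrix(
            G=800, times=t, alpha=2.0, beta=5.5e-4,
            sigma0=0.3, sigma1=1e-4, sigma_eps=0.02, rng=rng)
        fit = fit_lme(Y)
        assert fit.alpha == pytest.approx(2.0, abs=4 * fit.bse[0])
        assert fit.beta == pytest.approx(5.5e-4, abs=4 * fit.bse[1])
        assert np.sqrt(fit.sigma0_sq) == pytest.approx(0.3, rel=0.15)
        assert np.sqrt(fit.sigma1_sq) == pytest.approx(1e-4, rel=0.15)
        assert np.sqrt(fit.sigma_eps_sq) == pytest.approx(0.02, rel=0.15)

    def test_two_timepoints_near_interpolation(self):
        # growth-like panels have positively correlated node intercepts and
        # slopes (bigger bulge grows faster); the two-scan ML solution then
        # sits on the sigma_eps boundary and reproduces both observed
        # surfaces per node
        rng = np.random.default_rng(9)
        t = np.array([0.0, 365.0])
        a = 2.0 + rng.normal(0, 0.2, size=200)
        s = 1e-3 + 5e-4 * (a - 2.0) + rng.normal(0, 5e-5, size=200)
        Y = make_Y(a[:, None] + np.outer(s, t), t)
        fit = fit_lme(Y)
        rmse = np.sqrt(np.mean((fit.fittedvalues() - Y.values) ** 2))
        assert rmse < 1e-3 * np.abs(Y.values).mean()

    def test_node_permutation_invariance(self):
        rng = np.random.default_rng(5)
        t = np.array([0.0, 500.0, 1000.0])
        Y, _ = simulate_response_matrix(50, t, 2.0, 5e-4, 0.2, 5e-5, 0.02, rng)
        perm = rng.permutation(50)
        fit_a = fit_lme(Y)
        fit_b = fit_lme(make_Y(Y.values[perm], t))
        assert fit_b.alpha == pytest.approx(fit_a.alpha, abs=1e-6)
        assert fit_b.beta == pytest.approx(fit_a.beta, abs=1e-9)
        assert fit_b.sigma0_sq == pytest.approx(fit_a.sigma0_sq, rel=1e-4)
        np.testing.assert_allclose(fit_b.b0, fit_a.b0[perm], atol=1e-6)

    def test_pinned_zero_random_effects_reduce_to_pooled_ols(self):
        rng = np.random.default_rng(17)
        t = np.array([0.0, 300.0, 900.0])
        Y, _ = simulate_response_matrix(60, t, 2.0, 5e-4, 0.2, 5e-5, 0.05, rng)
        theta = np.log([VARIANCE_FLOOR, VARIANCE_FLOOR, 0.05**2])
        gamma, _, _ = _profile(theta, Y.values, Y.times)
        # pooled OLS over all G*T observations
        X = np.column_stack([np.ones(3), t])
        Xs = np.tile(X, (60, 1))
        beta_ols = np.linalg.lstsq(Xs, Y.values.ravel(), rcond=None)[0]
        np.testing.assert_allclose(gamma, beta_ols, atol=1e-8)

    def test_blup_shrinks_node_trajectories_toward_population_line(self):
        rng = np.random.default_rng(31)
        t = np.array([0.0, 400.0, 800.0, 1200.0])
        Y, _ = simulate_response_matrix(300, t, 2.0, 5.5e-4, 0.3, 1e-4, 0.02,
                                        rng)
        fit = fit_lme(Y)
        assert fit.sigma_eps_sq > 0
        X = np.column_stack([np.ones(4), t])
        ols = np.linalg.lstsq(X, Y.values.T, rcond=None)[0].T  # (G, 2)
        dev_ols = ols - np.array([fit.alpha, fit.beta])
        B = np.column_stack([fit.b0, fit.b1])
        norm_blup = np.linalg.norm(X @ B.T, axis=0)
        norm_ols = np.linalg.norm(X @ dev_ols.T, axis=0)
        assert np.all(norm_blup <= norm_ols + 1e-10)

    def test_blup_means_are_zero(self):
        rng = np.random.default_rng(8)
        t = np.array([0.0, 350.0, 800.0])
        Y, _ = simulate_response_matrix(200, t, 2.0, 5e-4, 0.25, 8e-5, 0.02,
                                        rng)
        fit = fit_lme(Y)
        assert abs(fit.b0.mean()) < 1e-6 * max(abs(fit.alpha), 1.0)
        assert abs(fit.b1.mean()) < 1e-6 * max(abs(fit.beta), 1e-4)


class TestNegLogLikelihood:
    def test_matches_dense_covariance_oracle(self):
        rng = np.random.default_rng(3)
        t = np.array([0.0, 200.0, 600.0])
        Y = make_Y(rng.normal(2.0, 0.3, size=(2, 3)), t)
        theta = np.log([0.09, 1e-8, 4e-4])
        got = neg_log_likelihood(theta, Y)
        # independent oracle: stacked 6-dim Gaussian with block-diagonal
        # covariance evaluated at the GLS fixed effects
        s0, s1, se = np.exp(theta)
        V = s0 * np.ones((3, 3)) + s1 * np.outer(t, t) + se * np.eye(3)
        Sigma = np.kron(np.eye(2), V)
        X = np.column_stack([np.ones(3), t])
        Xs = np.tile(X, (2, 1))
        y = Y.values.ravel()
        Si = np.linalg.inv(Sigma)
        gamma = np.linalg.solve(Xs.T @ Si @ Xs, Xs.T @ Si @ y)
        expected = -2.0 * multivariate_normal.logpdf(y, mean=Xs @ gamma,
                                                     cov=Sigma)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_location_invariance(self):
        rng = np.random.default_rng(4)
        t = np.array([0.0, 100.0])
        Y = make_Y(rng.normal(size=(5, 2)), t)
        Yc = make_Y(Y.values + 13.7, t)
        theta = np.log([0.5, 1e-6, 0.1])
        assert neg_log_likelihood(theta, Y) == pytest.approx(
            neg_log_likelihood(theta, Yc), abs=1e-8)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(6)
        t = np.array([0.0, 250.0, 700.0])
        Y = make_Y(rng.normal(2.0, 0.2, size=(4, 3)), t)
        theta = np.log([0.04, 1e-8, 1e-3])
        s = 3.0
        Ys = make_Y(s * Y.values, t)
        theta_s = theta + 2 * np.log(s)
        # -2LL picks up 2*G*T*log(s) from the Jacobian of the scaling
        assert neg_log_likelihood(theta_s, Ys) == pytest.approx(
            neg_log_likelihood(theta, Y) + 2 * 4 * 3 * np.log(s), abs=1e-8)

    def test_nonfinite_theta_rejected(self):
        Y = make_Y(np.ones((3, 2)), [0.0, 10.0])
        with pytest.raises(ValueError):
            neg_log_likelihood(np.array([np.nan, 0.0, 0.0]), Y)


class TestPredictNodes:
    @pytest.fixture(scope="class")
    def fit(self):
        rng = np.random.default_rng(12)
        t = np.array([0.0, 400.0, 900.0])
        Y, _ = simulate_response_matrix(30, t, 2.0, 5e-4, 0.2, 5e-5, 0.01, rng)
        return fit_lme(Y)

    def test_intercept_at_baseline(self, fit):
        np.testing.assert_allclose(predict_nodes(fit, 0.0),
                                   fit.alpha + fit.b0, atol=0)

    def test_linear_increment(self, fit):
        d = predict_nodes(fit, 365.0) - predict_nodes(fit, 0.0)
        np.testing.assert_allclose(d, 365.0 * (fit.beta + fit.b1), rtol=1e-12)

    def test_midpoint_average_and_colinearity(self, fit):
        p0 = predict_nodes(fit, 100.0)
        p1 = predict_nodes(fit, 500.0)
        pm = predict_nodes(fit, 300.0)
        np.testing.assert_allclose(pm, 0.5 * (p0 + p1), rtol=1e-12)


class TestPatientModel:
    def test_all_fu_fits_all_responses(self, small_results):
        assert len(small_results.fits) == 6
        for fit in small_results.fits.values():
            assert fit.converged
            assert len(fit.times) == 4
        assert small_results.held_out_times == []

    def test_exclude_last_holds_out_final_scan(self, small_patient,
                                               small_param):
        series, _ = small_patient
        res = AneurysmGrowthModel(series, small_param).fit("exclude_last")
        for fit in res.fits.values():
            assert len(fit.times) == 3
        assert res.held_out_times == [float(series.times_days[-1])]

    def test_exclude_last_needs_three_scans(self, small_patient, small_param):
        series, _ = small_patient
        import copy
        short = copy.copy(series)
        short.scans = series.scans[:2]
        param2 = copy.deepcopy(small_param)
        for lp in param2.layers.values():
            lp.centerlines = lp.centerlines[:2]
            lp.grids = lp.grids[:2]
            lp.slices = lp.slices[:2]
        with pytest.raises(RegimeError):
            AneurysmGrowthModel(short, param2).fit(FitRegime.EXCLUDE_LAST)

    def test_summary_mentions_all_fits(self, small_results):
        text = small_results.summary()
        assert "radius" in text and "centerline_x" in text
        assert "outer_wall" in text and "lumen" in text


class TestForecastGeometry:
    def test_reproduces_training_scan_when_noise_free(self, noise_free_patient,
                                                      noise_free_results):
        series, _ = noise_free_patient
        res = noise_free_results
        t_obs = float(series.times_days[2])
        fc = res.forecast(t_obs)
        for layer in (Layer.OUTER_WALL, Layer.LUMEN):
            lp = res.param.layers[layer]
            from aaaforecast import inverse_map
            observed = inverse_map(lp.grids[2], lp.centerlines[2])
            _, _, cloud = fc[layer]
            assert np.abs(cloud - observed).max() < 1e-6

    def test_forecast_radii_track_generating_growth(self, noise_free_patient,
                                                    noise_free_results):
        series, gt = noise_free_patient
        res = noise_free_results
        t_last = float(series.times_days[-1])
        fc_last = res.forecast(t_last)
        fc_next = res.forecast(t_last + 365.0)
        g = gt.config.g
        for layer in (Layer.OUTER_WALL, Layer.LUMEN):
            _, grid_last, _ = fc_last[layer]
            _, grid_next, _ = fc_next[layer]
            growth = grid_next.radii - grid_last.radii
            # apex nodes grow at the configured rate
            k_apex = np.argmin(np.abs(grid_last.z_axis - gt.config.z0))
            apex_growth = growth[k_apex].max()
            assert apex_growth == pytest.approx(g * 365.0, rel=0.05)
            # neck nodes grow ~0; allow parameterization-level jitter
            assert growth.min() > -1e-3

    def test_forecast_is_affine_in_time(self, small_results):
        fc0 = small_results.forecast(0.0)
        fc1 = small_results.forecast(800.0)
        fcm = small_results.forecast(400.0)
        for layer in (Layer.OUTER_WALL, Layer.LUMEN):
            mid = 0.5 * (fc0[layer][1].radii + fc1[layer][1].radii)
            np.testing.assert_allclose(fcm[layer][1].radii, mid, atol=1e-10)


class TestStatsmodelsCrossCheck:
    def test_ml_estimates_agree_with_mixedlm(self):
        # independent route: statsmodels MixedLM with diagonal random-effects
        # covariance, ML estimation, on a small panel
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.regression.mixed_linear_model import MixedLMParams

        rng = np.random.default_rng(77)
        t = np.array([0.0, 1.0, 2.0, 3.0])  # scaled time for conditioning
        Y, _ = simulate_response_matrix(80, t, 2.0, 0.15, 0.3, 0.08, 0.05,
                                        rng)
        fit = fit_lme(Y)

        G, T = Y.values.shape
        df = pd.DataFrame({
            "y": Y.values.ravel(),
            "t": np.tile(t, G),
            "node": np.repeat(np.arange(G), T),
        })
        free = MixedLMParams.from_components(
            fe_params=np.ones(2), cov_re=np.eye(2))
        md = sm.MixedLM.from_formula("y ~ t", groups="node",
                                     re_formula="~t", data=df)
        mf = md.fit(free=free, reml=False, method="lbfgs")
        assert fit.alpha == pytest.approx(mf.fe_params.iloc[0], abs=1e-4)
        assert fit.beta == pytest.approx(mf.fe_params.iloc[1], abs=1e-4)
        cov_re = mf.cov_re.to_numpy()
        assert fit.sigma0_sq == pytest.approx(cov_re[0, 0], rel=1e-2)
        assert fit.sigma1_sq == pytest.approx(cov_re[1, 1], rel=1e-2)
        assert fit.sigma_eps_sq == pytest.approx(mf.scale, rel=1e-2)
        assert fit.loglik == pytest.approx(mf.llf, abs=1e-3)


class TestPlotting:
    def test_forecast_radius_map_renders(self, small_results):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        ax = small_results.plot_forecast(1540.0)
        assert ax.get_xlabel().startswith("θ")
        plt.close(ax.figure)
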