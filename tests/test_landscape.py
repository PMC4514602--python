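"""Landscape-level estimator: prediction, weighting, bootstrap and areas."""

import numpy as np
import pytest

import occuchain as oc
from occuchain.landscape import delta_method_psi_variance, draw_beta, psi_covariance


class TestPrediction:
    def test_zero_coefficients_give_half(self, sim_dataset_and_fit):
        _, ds, fit = sim_dataset_and_fit
        zeroed = oc.FittedModel(
            spec=fit.spec, beta=np.zeros_like(fit.beta), beta_names=fit.beta_names,
            vcov=None, loglik=0.0, n_params=fit.n_params, aic=0.0, deviance=0.0,
            converged=True, n_sites=ds.n_sites,
        )
        np.testing.assert_allclose(oc.predict_site_psi(zeroed, ds), 0.5)

    def test_intercept_only_prediction_closed_form(self, sim_dataset_and_fit):
        # inv_logit of the published top-model intercept, with covariates 0
        assert float(oc.inv_logit(5.582)) == pytest.approx(0.99626, abs=1e-4)


class TestOverallOccupancy:
    def test_constant_psi_is_fixed_point(self):
        w = np.array([0.25, 0.25, 0.5])
        assert oc.overall_occupancy(np.full(3, 0.42), w) == pytest.approx(0.42)

    def test_hand_arithmetic(self):
        assert oc.overall_occupancy([0.2, 0.8], [0.25, 0.75]) == pytest.approx(0.65)

    def test_uniform_weights_equal_unweighted_mean(self, sim_dataset_and_fit):
        _, ds, fit = sim_dataset_and_fit
        psi = oc.predict_site_psi(fit, ds)
        w = np.full(ds.n_sites, 1.0 / ds.n_sites)
        assert oc.overall_occupancy(psi, w) == pytest.approx(float(psi.mean()))

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            oc.overall_occupancy([0.5, 0.5], [0.4, 0.4])

    def test_weighted_mean_bounded_by_extremes(self, sim_dataset_and_fit):
        _, ds, fit = sim_dataset_and_fit
        psi = oc.predict_site_psi(fit, ds)
        w = oc.area_weights(ds)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        est = oc.overall_occupancy(psi, w)
        assert psi.min() <= est <= psi.max()


class TestBetaDraws:
    def test_zero_vcov_draws_collapse_to_point(self, sim_dataset_and_fit):
        _, ds, fit = sim_dataset_and_fit
        frozen = oc.FittedModel(
            spec=fit.spec, beta=fit.beta, beta_names=fit.beta_names,
            vcov=np.zeros_like(fit.vcov), loglik=fit.loglik, n_params=fit.n_params,
            aic=fit.aic, deviance=fit.deviance, converged=True, n_sites=ds.n_sites,
        )
        draws = draw_beta(frozen, B=10, seed=0)
        np.testing.assert_allclose(
            draws.beta, np.broadcast_to(fit.beta, draws.beta.shape), atol=1e-12
        )
        assert np.abs(psi_covariance(draws, ds)).max() < 1e-20

    def test_deterministic_given_seed(self, sim_dataset_and_fit):
        _, _, fit = sim_dataset_and_fit
        d1 = draw_beta(fit, B=100, seed=33)
        d2 = draw_beta(fit, B=100, seed=33)
        np.testing.assert_array_equal(d1.beta, d2.beta)

    def test_marginal_variance_matches_vcov(self, sim_dataset_and_fit):
        _, _, fit = sim_dataset_and_fit
        draws = draw_beta(fit, B=100_000, seed=1)
        sample_var = draws.beta[:, 0].var(ddof=1)
        assert sample_var == pytest.approx(fit.vcov[0, 0], rel=0.03)


class TestPsiCovariance:
    def test_diagonal_is_sample_variance(self, sim_dataset_and_fit):
        _, ds, fit = sim_dataset_and_fit
        draws = draw_beta(fit, B=100, seed=5)
        cov = psi_covariance(draws, ds)
        X = oc.build_design_matrix(ds, fit.spec.psi_terms)
        psi_draws = oc.inv_logit(draws.beta[:, : X.shape[1]] @ X.T)
        np.testing.assert_allclose(np.diag(cov), psi_draws.var(axis=0, ddof=1), rtol=1e-10)

    def test_shared_covariate_rows_perfectly_correlated(self, sim_dataset_and_fit):
        _, ds, fit = sim_dataset_and_fit
        # duplicate site 0's covariate row into site 1
        ds2 = oc.SurveyDataset(
            site_ids=ds.site_ids,
            histories=ds.histories,
            covariates=ds.covariates.copy().pipe(
                lambda t: t.set_axis(range(len(t))).assign(
                    **{c: t[c].where(t.index != 1, t[c].iloc[0]) for c in t.columns}
                )
            ),
            forest_area=ds.forest_area,
        )
        cov = psi_covariance(draw_beta(fit, B=50, seed=2), ds2)
        r = cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])
        assert r == pytest.approx(1.0, abs=1e-10)


class TestOverallSE:
    def test_delta_and_bootstrap_variances_agree(self, sim_dataset_and_fit):
        _, ds, fit = sim_dataset_and_fit
        var_delta = delta_method_psi_variance(fit, ds)
        cov = psi_covariance(draw_beta(fit, B=5000, seed=3), ds)
        var_boot = np.diag(cov)
        # aggregate agreement (single-site ratios are noisier)
        assert var_boot.sum() == pytest.approx(var_delta.sum(), rel=0.25)

    def test_se_stable_under_site_reordering(self, sim_dataset_and_fit):
        _, ds, fit = sim_dataset_and_fit
        se1 = oc.overall_se(fit, ds, B=200, seed=4)
        order = np.arange(ds.n_sites)[::-1]
        ds_rev = oc.SurveyDataset(
            site_ids=[ds.site_ids[i] for i in order],
            histories=[ds.histories[i] for i in order],
            covariates=ds.covariates.iloc[order].reset_index(drop=True),
            forest_area=ds.forest_area[order],
        )
        se2 = oc.overall_se(fit, ds_rev, B=200, seed=4)
        assert se2 == pytest.approx(se1, rel=0.2)

    def test_doubling_draws_changes_se_modestly(self, sim_dataset_and_fit):
        _, ds, fit = sim_dataset_and_fit
        se_b = oc.overall_se(fit, ds, B=100, seed=6)
        se_2b = oc.overall_se(fit, ds, B=200, seed=6)
        assert abs(se_2b - se_b) / se_b < 0.25

    def test_single_site_collapses_to_site_sd(self, sim_dataset_and_fit):
        _, ds, fit = sim_dataset_and_fit
        one = oc.SurveyDataset(
            site_ids=[ds.site_ids[0]],
            histories=[ds.histories[0]],
            covariates=ds.covariates.iloc[[0]].reset_index(drop=True),
            forest_area=[float(ds.forest_area[0])],
        )
        se = oc.overall_se(fit, one, B=100, seed=7)
        var = delta_method_psi_variance(fit, one)
        assert se == pytest.approx(float(np.sqrt(var[0])), rel=1e-9)


class TestOccupiedArea:
    def test_published_area_arithmetic(self):
        # published overall estimate x landscape forest area
        rep = oc.occupied_area(0.637, 21_167.0, 0.537)
        assert rep.occupied_area_km2 == pytest.approx(13_483, abs=1)
        assert rep.naive_area_km2 == pytest.approx(11_367, abs=1)
        assert rep.underestimation_km2 == pytest.approx(2_116, abs=1)
        assert rep.underestimation_pct == pytest.approx(15.7, abs=0.1)

    def test_zero_occupancy_zero_area(self):
        rep = oc.occupied_area(0.0, 100.0, 0.0)
        assert rep.occupied_area_km2 == 0.0

    def test_landscape_estimate_bundle_consistent(self, sim_dataset_and_fit):
        _, ds, fit = sim_dataset_and_fit
        est = oc.landscape_estimate(fit, ds, B=100, seed=8)
        assert est.occupied_area_km2 == pytest.approx(
            est.overall_psi * est.total_forest_area_km2
        )
        assert est.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert est.site_psi.min() <= est.overall_psi <= est.site_psi.max()
        table = est.site_table(ds)
        assert len(table) == ds.n_sites
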