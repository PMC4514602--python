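"""Likelihood core: link functions, the forward recursion against the
enumeration oracle, normalization, and reduction identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from itertools import product

import occuchain as oc
from occuchain.occupancy_models import SiteParameters, negative_log_likelihood
from conftest import brute_force_markov_likelihood


class TestLinks:
    def test_inv_logit_values(self):
        assert oc.inv_logit(0.0) == pytest.approx(0.5)
        assert oc.inv_logit(50.0) == pytest.approx(1.0, abs=1e-9)
        assert oc.inv_logit(-50.0) == pytest.approx(0.0, abs=1e-9)
        assert oc.inv_logit(np.log(1 / 9)) == pytest.approx(0.1)

    def test_logit_inverts(self):
        x = np.linspace(-8, 8, 33)
        np.testing.assert_allclose(oc.logit(oc.inv_logit(x)), x, atol=1e-9)


class TestStationaryTheta0:
    def test_published_transition_estimates(self):
        # the two published intercept-only / top-model transition pairs
        assert oc.stationary_theta0(0.082, 0.962) == pytest.approx(0.683, abs=5e-4)
        assert oc.stationary_theta0(0.084, 0.953) == pytest.approx(0.084 / 0.131)

    def test_iid_chain_is_fixed_point(self):
        for t in (0.0, 0.3, 1.0):
            assert oc.stationary_theta0(t, t) == pytest.approx(t)

    def test_doubly_absorbing_chain_undefined(self):
        with pytest.raises(ValueError):
            oc.stationary_theta0(0.0, 1.0)

    def test_psi_weighted_variant(self):
        assert oc.psi_weighted_theta0(0.1, 0.9, 0.5) == pytest.approx(0.5)


class TestStandardLikelihood:
    def test_hand_computed_values(self):
        assert oc.site_likelihood_standard(1.0, 0.5, "10") == pytest.approx(0.25)
        # psi*0.7^2 + (1-psi) for an all-zero history
        assert oc.site_likelihood_standard(0.6, 0.3, "00") == pytest.approx(0.694)

    def test_all_missing_history_is_uninformative(self):
        assert oc.site_likelihood_standard(0.37, 0.9, [np.nan, np.nan]) == pytest.approx(1.0)

    def test_detection_impossible_when_unoccupied(self):
        assert oc.site_likelihood_standard(0.0, 0.9, "01") == 0.0


class TestMarkovLikelihood:
    def test_collapses_to_standard_when_always_present(self):
        sp = SiteParameters(1.0, 1.0, 1.0, 1.0, 0.5)
        assert oc.site_likelihood_markov(sp, "10") == pytest.approx(0.25)

    def test_brute_force_example(self):
        t0 = oc.stationary_theta0(0.3, 0.7)
        sp = SiteParameters(0.8, 0.3, 0.7, t0, 0.6)
        h = np.array([1.0, 0.0, 1.0])
        expected = brute_force_markov_likelihood(0.8, 0.3, 0.7, t0, 0.6, h)
        assert oc.site_likelihood_markov(sp, h) == pytest.approx(expected, abs=1e-12)

    def test_unoccupied_site_cannot_yield_detections(self):
        sp = SiteParameters(0.0, 0.3, 0.7, 0.5, 0.6)
        assert oc.site_likelihood_markov(sp, "001") == 0.0

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=150, derandomize=True)
    def test_forward_recursion_equals_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        psi, p = rng.random(2)
        theta = rng.uniform(0.01, 0.99)
        theta_prime = rng.uniform(0.01, 0.99)
        theta0 = oc.stationary_theta0(theta, theta_prime)
        K = int(rng.integers(1, 11))
        h = rng.integers(0, 2, K).astype(float)
        if K > 2 and rng.random() < 0.5:
            h[rng.integers(0, K)] = np.nan
        sp = SiteParameters(psi, theta, theta_prime, theta0, p)
        got = oc.site_likelihood_markov(sp, h)
        want = brute_force_markov_likelihood(psi, theta, theta_prime, theta0, p, h)
        assert got == pytest.approx(want, rel=1e-10, abs=1e-12)

    @pytest.mark.parametrize("K", [1, 2, 3, 4])
    def test_likelihood_normalizes_over_histories(self, K):
        for model in ("markov", "standard"):
            total = 0.0
            for h in product((0.0, 1.0), repeat=K):
                if model == "markov":
                    sp = SiteParameters(0.7, 0.25, 0.85, oc.stationary_theta0(0.25, 0.85), 0.55)
                    total += oc.site_likelihood_markov(sp, np.array(h))
                else:
                    total += oc.site_likelihood_standard(0.7, 0.55, np.array(h))
            assert total == pytest.approx(1.0, abs=1e-10)

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_reduction_to_standard_with_thinned_detection(self, seed):
        # iid presence chain (theta = theta' = theta0 = t) is a standard
        # model with detection t*p; t = 1 recovers p exactly
        rng = np.random.default_rng(seed)
        psi, t, p = rng.random(3)
        h = rng.integers(0, 2, int(rng.integers(1, 9))).astype(float)
        sp = SiteParameters(psi, t, t, t, p)
        assert oc.site_likelihood_markov(sp, h) == pytest.approx(
            oc.site_likelihood_standard(psi, t * p, h), rel=1e-10, abs=1e-12
        )
        sp1 = SiteParameters(psi, 1.0, 1.0, 1.0, p)
        assert oc.site_likelihood_markov(sp1, h) == pytest.approx(
            oc.site_likelihood_standard(psi, p, h), rel=1e-10, abs=1e-12
        )

    def test_all_zero_history_nonincreasing_in_psi(self):
        h = np.zeros(5)
        t0 = oc.stationary_theta0(0.3, 0.8)
        vals = [
            oc.site_likelihood_markov(SiteParameters(psi, 0.3, 0.8, t0, 0.6), h)
            for psi in np.linspace(0, 1, 21)
        ]
        assert np.all(np.diff(vals) <= 1e-12)

    def test_long_history_numerically_stable(self):
        sp = SiteParameters(0.9, 0.05, 0.95, oc.stationary_theta0(0.05, 0.95), 0.7)
        h = np.tile([1.0, 0.0], 250)
        like = oc.site_likelihood_markov(sp, h)
        assert 0.0 < like < 1.0 and np.isfinite(like)


class TestDatasetNLL:
    def test_single_site_intercept_only(self, toy_dataset):
        # beta = 0 puts psi = p = 0.5 everywhere
        spec = oc.ModelSpec(".", ".", dependence="standard")
        sub = oc.SurveyDataset(
            site_ids=["A"],
            histories=[np.array([1.0])],
            covariates=toy_dataset.covariates.iloc[[0]].reset_index(drop=True),
            forest_area=[100.0],
        )
        nll = negative_log_likelihood(np.zeros(2), spec, sub)
        assert nll == pytest.approx(-np.log(0.25))

    def test_all_missing_dataset_has_zero_nll(self, toy_dataset):
        sub = oc.SurveyDataset(
            site_ids=["A", "B"],
            histories=[np.array([np.nan, np.nan]), np.array([np.nan])],
            covariates=toy_dataset.covariates.reset_index(drop=True),
            forest_area=[100.0, 50.0],
        )
        for dep in ("standard", "markov"):
            spec = oc.ModelSpec(".", ".", dependence=dep)
            k = spec.n_params()
            assert negative_log_likelihood(np.zeros(k), spec, sub) == pytest.approx(0.0)

    def test_matches_sum_of_per_site_brute_force(self):
        ds = oc.simulate_dataset(oc.reference_truth(n_sites=3, fixed_k=5), seed=9)
        spec = oc.ModelSpec("LVS", "PropFor", dependence="markov")
        beta = np.array([0.4, -0.6, 0.2, 0.5, -1.5, 2.2])
        X_psi = oc.build_design_matrix(ds, spec.psi_terms)
        X_p = oc.build_design_matrix(ds, spec.p_terms)
        theta = float(oc.inv_logit(-1.5))
        theta_prime = float(oc.inv_logit(2.2))
        t0 = oc.stationary_theta0(theta, theta_prime)
        expected = 0.0
        for i in range(3):
            psi = float(oc.inv_logit(X_psi[i] @ beta[:2]))
            p = float(oc.inv_logit(X_p[i] @ beta[2:4]))
            expected -= np.log(
                brute_force_markov_likelihood(psi, theta, theta_prime, t0, p, ds.histories[i])
            )
        assert negative_log_likelihood(beta, spec, ds) == pytest.approx(expected, rel=1e-10)

    def test_wrong_beta_length_raises(self, toy_dataset):
        with pytest.raises(ValueError, match="length"):
            negative_log_likelihood(np.zeros(3), oc.ModelSpec(".", "."), toy_dataset)


class TestModelSpec:
    def test_name_follows_field_convention(self):
        spec = oc.ModelSpec("LVS*NDVI", "LVS+PropFor")
        assert spec.name == "psi(LVS*NDVI),thta0,thta1,p(LVS+PropFor)"
        assert spec.n_params() == 9
        std = oc.ModelSpec(".", ".", dependence="standard")
        assert std.name == "psi(.),p(.)" and std.n_params() == 2

    def test_intercept_only_markov_has_theta_block(self):
        spec = oc.ModelSpec(".", ".", dependence="markov")
        assert spec.n_params() == 4
        assert spec.beta_names()[-2:] == ["logit_theta", "logit_theta_prime"]
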