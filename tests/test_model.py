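"""Hierarchical CJS model: likelihood oracle, priors, transforms, kernels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from oracles import dataset_loglik
from procjs import (
    AgeMArraySet,
    AgeStructuredCJS,
    ConstantDetection,
    CovarianceSpec,
    ModelParams,
    PriorSpec,
    SeparatedPriorConfig,
    WishartPriorConfig,
    build_marrays,
)
from procjs.model import AgeTimeDetection
from procjs.transforms import expit, logit


def random_params(rng, T, detection="constant"):
    ni = T - 1
    if detection == "constant":
        det = ConstantDetection(p=float(rng.uniform(0.2, 0.8)))
    else:
        det = AgeTimeDetection(
            beta0=float(rng.normal(0, 0.5)),
            sigma_p_sy=float(rng.uniform(0.2, 1.0)),
            sigma_p_ad=float(rng.uniform(0.2, 1.0)),
            eps_sy=rng.normal(0, 0.4, ni),
            eps_ad=rng.normal(0, 0.4, ni),
        )
    return ModelParams(
        mu_ad=float(rng.normal(1, 0.3)),
        mu_juv=float(rng.normal(-1, 0.3)),
        cov=CovarianceSpec(
            float(rng.uniform(0.1, 1.0)),
            float(rng.uniform(0.1, 1.0)),
            float(rng.uniform(-0.9, 0.9)),
        ),
        eta_ad=rng.normal(1, 0.5, ni),
        eta_juv=rng.normal(-1, 0.5, ni),
        detection=det,
    )


class TestLogLikelihood:
    def test_empty_marray_gives_zero(self, rng):
        T = 4
        marr = AgeMArraySet(
            m_juv=np.zeros((T - 1, T), dtype=np.int64),
            m_ad=np.zeros((T - 1, T), dtype=np.int64),
        )
        model = AgeStructuredCJS(marr)
        assert model.log_likelihood(random_params(rng, T)) == 0.0

    def test_matches_latent_state_enumeration(self, micro, rng):
        """The m-array multinomial likelihood must equal the brute-force sum
        over every latent alive/dead path of every individual."""
        model = AgeStructuredCJS.from_histories(micro)
        for _ in range(5):
            params = random_params(rng, 3)
            p_vec = np.full(3, params.detection.p)
            oracle = dataset_loglik(micro, params.phi_ad, params.phi_juv, p_vec)
            assert np.isclose(model.log_likelihood(params), oracle, atol=1e-10)

    def test_matches_enumeration_on_simulated_micro_data(self, rng):
        from procjs import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(T=4, releases_per_occasion=2, rho=0.5, seed=8)
        histories, _ = simulate_dataset(cfg)
        model = AgeStructuredCJS.from_histories(histories)
        params = random_params(rng, 4)
        p_vec = np.full(4, params.detection.p)
        oracle = dataset_loglik(histories, params.phi_ad, params.phi_juv, p_vec)
        assert np.isclose(model.log_likelihood(params), oracle, atol=1e-10)

    def test_agetime_matches_enumeration(self, micro, rng):
        """Second-year detection: juvenile first re-encounters use p_sy."""
        model = AgeStructuredCJS.from_histories(micro, detection="age_time")
        params = random_params(rng, 3, detection="age_time")
        p_ad, p_sy = params.detection.p_vectors(3)
        oracle = dataset_loglik(
            micro, params.phi_ad, params.phi_juv, p_ad, p_sy
        )
        assert np.isclose(model.log_likelihood(params), oracle, atol=1e-10)

    def test_never_seen_row_shifts_by_log_complement(self, micro, rng):
        model = AgeStructuredCJS.from_histories(micro)
        params = random_params(rng, 3)
        base = model.log_likelihood(params)
        # add 3 never-re-encountered adults released at occasion 1 (0-based 0)
        m2 = AgeMArraySet(
            m_juv=model.data.m_juv.copy(), m_ad=model.data.m_ad.copy()
        )
        m2.m_ad[0, -1] += 3
        from procjs.marray import cell_probabilities

        p_never = cell_probabilities(
            params.phi_ad, params.phi_juv, params.detection.p, "ad", 0, 3
        )[-1]
        shifted = AgeStructuredCJS(m2).log_likelihood(params)
        assert np.isclose(shifted - base, 3 * np.log(p_never), atol=1e-10)

    def test_individual_order_invariance(self, small_dataset):
        hist, _ = small_dataset
        perm = np.random.default_rng(0).permutation(hist.n_individuals)
        from procjs import EncounterHistorySet

        shuffled = EncounterHistorySet(
            y=hist.y[perm], tau=hist.tau[perm], age_at_release=hist.age_at_release[perm]
        )
        assert np.array_equal(
            build_marrays(hist).m_juv, build_marrays(shuffled).m_juv
        )
        assert np.array_equal(
            build_marrays(hist).m_ad, build_marrays(shuffled).m_ad
        )

    def test_dimension_mismatch_rejected(self, small_marrays, rng):
        model = AgeStructuredCJS(small_marrays)  # T = 5
        with pytest.raises(ValueError, match="intervals"):
            model.log_likelihood(random_params(rng, 7))


class TestLogPrior:
    def test_separated_out_of_support(self, small_marrays, rng):
        model = AgeStructuredCJS(small_marrays, PriorSpec(SeparatedPriorConfig()))
        params = random_params(rng, 5)
        params.cov = CovarianceSpec(6.0, 0.3, 0.2)  # sigma above upper bound 5
        assert model.log_prior(params) == -np.inf

    def test_flat_rho_prior_only_enters_through_year_effects(
        self, small_marrays, rng
    ):
        model = AgeStructuredCJS(small_marrays, PriorSpec(SeparatedPriorConfig()))
        params = random_params(rng, 5)
        for rho in (0.2, 0.6):
            params.cov = CovarianceSpec(0.4, 0.4, rho)
            mvn = stats.multivariate_normal.logpdf(
                np.column_stack([params.eta_ad, params.eta_juv]),
                mean=[params.mu_ad, params.mu_juv],
                cov=params.cov.matrix,
            ).sum()
            if rho == 0.2:
                base = model.log_prior(params) - mvn
            else:
                assert np.isclose(
                    model.log_prior(params) - mvn, base, atol=1e-10
                )

    def test_inverse_wishart_density_closed_form(self):
        # hand-derived: log IW(I | nu=3, I) = -3 log 2 - log Gamma_2(3/2) - 1
        # with Gamma_2(3/2) = sqrt(pi) * Gamma(3/2) * Gamma(1) = pi / 2
        hand = -3 * np.log(2.0) - np.log(np.pi / 2.0) - 1.0
        assert np.isclose(
            stats.invwishart.logpdf(np.eye(2), df=3, scale=np.eye(2)), hand
        )

    def test_iw_prior_uses_invwishart_density(self, small_marrays, rng):
        model = AgeStructuredCJS(small_marrays, PriorSpec(WishartPriorConfig()))
        params = random_params(rng, 5)
        lp = model.log_prior(params)
        # subtracting every other analytic term must leave the IW density
        mvn = stats.multivariate_normal.logpdf(
            np.column_stack([params.eta_ad, params.eta_juv]),
            mean=[params.mu_ad, params.mu_juv],
            cov=params.cov.matrix,
        ).sum()
        means = stats.norm.logpdf([params.mu_ad, params.mu_juv]).sum()
        residual = lp - mvn - means
        assert np.isclose(
            residual,
            stats.invwishart.logpdf(params.cov.matrix, df=3, scale=np.eye(2)),
            atol=1e-10,
        )


class TestTransforms:
    @pytest.mark.parametrize(
        "covariance", [SeparatedPriorConfig(), WishartPriorConfig(),
                       SeparatedPriorConfig(sigma_halfnormal_variance=10.0)],
        ids=["separated", "iw", "halfnormal"],
    )
    @pytest.mark.parametrize("detection", ["constant", "age_time"])
    def test_round_trip(self, covariance, detection, small_marrays, rng):
        priors = PriorSpec(covariance=covariance)
        model = AgeStructuredCJS(small_marrays, priors, detection=detection)
        for _ in range(5):
            params = random_params(rng, 5, detection=detection)
            theta = model.unconstrain(params)
            back = model.constrain(theta)
            assert np.isclose(back.mu_ad, params.mu_ad, atol=1e-10)
            assert np.isclose(back.cov.sigma_ad, params.cov.sigma_ad, atol=1e-10)
            assert np.isclose(back.cov.rho, params.cov.rho, atol=1e-10)
            assert np.allclose(back.eta_juv, params.eta_juv, atol=1e-10)
            theta2 = model.unconstrain(back)
            assert np.allclose(theta, theta2, atol=1e-10)

    def test_simple_fixed_points(self):
        assert logit(0.5) == 0.0
        assert expit(0.0) == 0.5

    def test_boundary_rejected(self, small_marrays, rng):
        model = AgeStructuredCJS(small_marrays, PriorSpec(WishartPriorConfig()))
        params = random_params(rng, 5)
        params.cov = CovarianceSpec(0.5, 0.5, 1.0)
        with pytest.raises(ValueError, match="boundary"):
            model.unconstrain(params)


class TestKernelConsistency:
    """The jitted sampling target must equal log_lik + log_prior + log|J|."""

    @pytest.mark.parametrize(
        "covariance", [SeparatedPriorConfig(), WishartPriorConfig(),
                       SeparatedPriorConfig(sigma_halfnormal_variance=10.0)],
        ids=["separated", "iw", "halfnormal"],
    )
    @pytest.mark.parametrize("detection", ["constant", "age_time"])
    def test_kernel_equals_reference(self, covariance, detection, small_marrays, rng):
        priors = PriorSpec(covariance=covariance)
        model = AgeStructuredCJS(small_marrays, priors, detection=detection)
        for _ in range(10):
            params = random_params(rng, 5, detection=detection)
            theta = model.unconstrain(params)
            reference = model.log_posterior(params) + model.log_jacobian(theta)
            kernel = model.log_posterior_unconstrained(theta)
            assert np.isclose(kernel, reference, atol=1e-8)

    def test_prior_only_kernel(self, small_marrays, rng):
        model = AgeStructuredCJS(small_marrays, PriorSpec(SeparatedPriorConfig()))
        params = random_params(rng, 5)
        theta = model.unconstrain(params)
        reference = model.log_prior(params) + model.log_jacobian(theta)
        kernel = model.log_posterior_unconstrained(theta, include_likelihood=False)
        assert np.isclose(kernel, reference, atol=1e-8)


class TestModelParamsSerialization:
    @pytest.mark.parametrize("detection", ["constant", "age_time"])
    def test_json_round_trip(self, detection, rng):
        params = random_params(rng, 5, detection=detection)
        back = ModelParams.from_json(params.to_json())
        assert np.isclose(back.mu_ad, params.mu_ad)
        assert np.allclose(back.eta_ad, params.eta_ad)
        assert np.isclose(back.cov.rho, params.cov.rho)
        if detection == "age_time":
            assert np.allclose(back.detection.eps_sy, params.detection.eps_sy)
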