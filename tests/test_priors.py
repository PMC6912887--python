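"""Prior machinery: covariance construction and implied-prior diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from procjs import (
    CovarianceSpec,
    SeparatedPriorConfig,
    WishartPriorConfig,
    build_covariance,
    decompose_covariance,
    implied_prior_report,
    sample_inverse_wishart_prior,
    sample_separated_prior,
)

N_BIG = 100_000


@pytest.fixture(scope="module")
def iw_draws():
    return sample_inverse_wishart_prior(WishartPriorConfig(), N_BIG, seed=7)


@pytest.fixture(scope="module")
def sep_draws():
    return sample_separated_prior(SeparatedPriorConfig(), N_BIG, seed=7)


class TestBuildCovariance:
    @pytest.mark.parametrize(
        "spec, expected",
        [
            (
                CovarianceSpec(np.sqrt(0.1), np.sqrt(0.1), 0.0),
                [[0.1, 0.0], [0.0, 0.1]],
            ),
            (
                CovarianceSpec(np.sqrt(0.1), np.sqrt(0.1), 0.5),
                [[0.1, 0.05], [0.05, 0.1]],
            ),
        ],
    )
    def test_matrix_entries(self, spec, expected):
        assert np.allclose(build_covariance(spec), expected)

    def test_perfect_correlation_is_singular(self):
        m = build_covariance(CovarianceSpec(1.0, 2.0, 1.0))
        assert np.isclose(np.linalg.det(m), 0.0)

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(sigma_ad=-1.0, sigma_juv=1.0, rho=0.0), "sigma_ad"),
            (dict(sigma_ad=1.0, sigma_juv=0.0, rho=0.0), "sigma_juv"),
            (dict(sigma_ad=1.0, sigma_juv=1.0, rho=1.5), "rho"),
        ],
    )
    def test_invalid_components_name_the_field(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            CovarianceSpec(**kwargs)

    @settings(deadline=None, max_examples=50)
    @given(
        s1=st.floats(1e-3, 50.0),
        s2=st.floats(1e-3, 50.0),
        rho=st.floats(-0.999, 0.999),
    )
    def test_decompose_round_trip(self, s1, s2, rho):
        spec = CovarianceSpec(s1, s2, rho)
        back = decompose_covariance(build_covariance(spec))
        assert np.isclose(back.sigma_ad, s1, atol=1e-12, rtol=1e-9)
        assert np.isclose(back.sigma_juv, s2, atol=1e-12, rtol=1e-9)
        assert np.isclose(back.rho, rho, atol=1e-9)


class TestInverseWishartPrior:
    def test_rejects_bad_scale(self):
        with pytest.raises(ValueError, match="positive definite"):
            WishartPriorConfig(scale=np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_rho_marginal_is_uniform(self, iw_draws):
        # under InvWishart(K+1, I) the correlation marginal is Uniform(-1, 1)
        ks = stats.kstest(iw_draws.draws["rho"], stats.uniform(-1, 2).cdf)
        assert ks.pvalue > 0.01

    def test_variance_marginal_median(self, iw_draws):
        # each variance is marginally InvGamma(shape (nu-K+1)/2 = 1, rate 1/2)
        expected = float(stats.invgamma.median(1.0, scale=0.5))
        assert np.isclose(expected, 0.5 / np.log(2), atol=1e-12)
        med = np.median(iw_draws.draws["sigma_ad"] ** 2)
        assert abs(med - expected) < 0.02

    def test_sigma_absrho_dependence(self, iw_draws):
        # the pathology: under IW(K+1, I) larger sigma co-occurs with larger
        # |rho| (rank correlation ~ +0.5, cross-checked against scipy's
        # invwishart sampler), while the signed rho stays symmetric
        r_abs = stats.spearmanr(
            iw_draws.draws["sigma_ad"], iw_draws.draws["rho"].abs()
        ).statistic
        assert r_abs > 0.2
        r_signed = stats.spearmanr(
            iw_draws.draws["sigma_ad"], iw_draws.draws["rho"]
        ).statistic
        assert abs(r_signed) < 0.02

    def test_precision_mean_matches_wishart(self):
        cfg = WishartPriorConfig()
        rng_draws = sample_inverse_wishart_prior(cfg, 20_000, seed=3)
        # reconstruct the precision matrices and compare the mean to df*scale
        precs = []
        for _, row in rng_draws.draws.iterrows():
            cov = build_covariance(
                CovarianceSpec(row.sigma_ad, row.sigma_juv, row.rho)
            )
            precs.append(np.linalg.inv(cov))
        mean_prec = np.mean(precs, axis=0)
        assert np.allclose(mean_prec, cfg.df * cfg.scale, atol=0.08)

    def test_seeded_reproducibility(self):
        a = sample_inverse_wishart_prior(WishartPriorConfig(), 5, seed=11)
        b = sample_inverse_wishart_prior(WishartPriorConfig(), 5, seed=11)
        assert a.draws.equals(b.draws)


class TestSeparatedPrior:
    def test_uniform_moments(self, sep_draws):
        df = sep_draws.draws
        assert abs(df["rho"].mean()) < 0.02
        assert abs(df["sigma_ad"].mean() - 2.5) < 0.02

    def test_components_independent(self, sep_draws):
        df = sep_draws.draws
        r = stats.spearmanr(df["sigma_ad"], df["rho"]).statistic
        assert abs(r) < 0.02

    def test_independence_chi2_grid(self, sep_draws):
        df = sep_draws.draws
        s_bins = np.quantile(df["sigma_ad"], np.linspace(0, 1, 11))
        r_bins = np.quantile(df["rho"], np.linspace(0, 1, 11))
        table, _, _ = np.histogram2d(df["sigma_ad"], df["rho"], bins=[s_bins, r_bins])
        chi2 = stats.chi2_contingency(table)
        assert chi2.pvalue > 0.01

    def test_halfnormal_option(self):
        cfg = SeparatedPriorConfig(sigma_halfnormal_variance=10.0)
        d = sample_separated_prior(cfg, 50_000, seed=5).draws
        # half-normal mean = sd * sqrt(2/pi)
        assert abs(d["sigma_ad"].mean() - np.sqrt(10.0) * np.sqrt(2 / np.pi)) < 0.05

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            SeparatedPriorConfig(sigma_lower=3.0, sigma_upper=2.0)
        with pytest.raises(ValueError):
            SeparatedPriorConfig(rho_lower=-2.0)

    def test_single_draw_reproducible(self):
        a = sample_separated_prior(SeparatedPriorConfig(), 1, seed=42)
        b = sample_separated_prior(SeparatedPriorConfig(), 1, seed=42)
        assert a.draws.equals(b.draws)


class TestImpliedPriorReport:
    def test_separated_report_independence(self, sep_draws):
        rep = implied_prior_report(sep_draws)
        assert all(abs(v) < 0.02 for v in rep["rank_correlations"].values())
        assert "warning" not in rep

    def test_iw_rho_median_and_variance_floor(self, iw_draws):
        rep = implied_prior_report(iw_draws)
        assert abs(rep["quantiles"]["rho"]["q50"]) < 0.02
        # the implied variance prior puts almost no mass below ~0.1: the
        # 2.5% quantile of InvGamma(1, 1/2) is 0.5/log(1/0.025) = 0.1355
        assert rep["quantiles"]["sigma2_ad"]["q2.5"] > 0.1

    def test_small_sample_flagged_not_fatal(self):
        d = sample_separated_prior(SeparatedPriorConfig(), 50, seed=1)
        rep = implied_prior_report(d)
        assert "warning" in rep

    def test_csv_round_trip(self, tmp_path):
        from procjs import PriorDrawSet

        d = sample_separated_prior(SeparatedPriorConfig(), 20, seed=1)
        path = tmp_path / "draws.csv"
        d.to_csv(path)
        back = PriorDrawSet.from_csv(path)
        assert np.allclose(back.draws.to_numpy(), d.draws.to_numpy())
        assert back.parameterization == "separated"
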