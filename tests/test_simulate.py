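"""Simulator: annual rates, latent states, detections and composition."""

import numpy as np
import pytest

from procjs import (
    AnnualRates,
    EncounterHistorySet,
    SimulationConfig,
    draw_annual_rates,
    simulate_dataset,
    simulate_detections,
    simulate_latent_states,
)
from procjs.transforms import expit, logit


def near_certain_rates(T, phi=1.0 - 1e-9):
    eta = np.full(T - 1, logit(phi))
    return AnnualRates(
        phi_ad=expit(eta),
        phi_juv=expit(eta),
        logit_ad=eta,
        logit_juv=eta,
        rho_true=0.0,
    )


class TestDrawAnnualRates:
    def test_degenerate_means_hit_target_survival(self):
        # mean logit survival 1 / -1 correspond to rates 0.731 / 0.269
        cfg = SimulationConfig(sigma_ad=0.0, sigma_juv=0.0, rho=0.0, T=6)
        rates = draw_annual_rates(cfg, seed=0)
        assert np.allclose(rates.phi_ad, expit(1.0))
        assert np.allclose(rates.phi_juv, expit(-1.0))
        assert np.allclose(rates.phi_ad, 0.731, atol=5e-4)
        assert np.allclose(rates.phi_juv, 0.269, atol=5e-4)

    def test_perfect_correlation_aligns_standardized_effects(self):
        cfg = SimulationConfig(rho=1.0, T=8)
        rates = draw_annual_rates(cfg, seed=1)
        dev_ad = rates.logit_ad - cfg.mu_ad
        dev_juv = rates.logit_juv - cfg.mu_juv
        assert np.allclose(dev_ad, dev_juv, atol=1e-9)
        assert rates.rho_true == 1.0

    def test_sample_moments_matched_exactly(self):
        cfg = SimulationConfig(rho=0.37, T=10)
        rates = draw_annual_rates(cfg, seed=2)
        eta = np.column_stack([rates.logit_ad, rates.logit_juv])
        assert np.allclose(eta.mean(axis=0), [1.0, -1.0], atol=1e-10)
        emp = np.cov(eta, rowvar=False)
        assert np.isclose(emp[0, 0], 0.1, atol=1e-10)
        assert np.isclose(emp[1, 1], 0.1, atol=1e-10)
        assert np.isclose(emp[0, 1] / 0.1, 0.37, atol=1e-10)

    def test_unmatched_draws_vary(self):
        cfg = SimulationConfig(rho=0.0, T=10, match_sample_moments=False)
        rates = draw_annual_rates(cfg, seed=2)
        emp = np.cov(
            np.column_stack([rates.logit_ad, rates.logit_juv]), rowvar=False
        )
        assert not np.isclose(emp[0, 0], 0.1, atol=1e-6)

    def test_random_rho_recorded(self):
        cfg = SimulationConfig(rho="random", T=5)
        r1 = draw_annual_rates(cfg, seed=3)
        r2 = draw_annual_rates(cfg, seed=4)
        assert -1 <= r1.rho_true <= 1
        assert r1.rho_true != r2.rho_true


class TestLatentStates:
    def test_certain_survival_keeps_everyone_alive(self):
        cfg = SimulationConfig(T=5, releases_per_occasion=40)
        z, tau, _ = simulate_latent_states(near_certain_rates(5), cfg, seed=0)
        cols = np.arange(5)
        after = cols[None, :] >= tau[:, None]
        assert np.all(z[after] == 1)

    def test_certain_death_kills_everyone(self):
        cfg = SimulationConfig(T=5, releases_per_occasion=40)
        z, tau, _ = simulate_latent_states(near_certain_rates(5, phi=1e-9), cfg, seed=0)
        cols = np.arange(5)
        after = cols[None, :] > tau[:, None]
        assert np.all(z[after] == 0)

    def test_death_is_absorbing(self):
        cfg = SimulationConfig(T=8, releases_per_occasion=100, rho=0.0)
        rates = draw_annual_rates(cfg, seed=5)
        z, tau, _ = simulate_latent_states(rates, cfg, seed=6)
        # once 0 after release, never 1 again
        for i in range(z.shape[0]):
            alive = z[i, tau[i] :]
            drops = np.diff(alive.astype(int))
            assert np.all(drops <= 0) or np.any(alive == 0)
            if np.any(alive == 0):
                first_dead = np.argmin(alive)
                assert np.all(alive[first_dead:] == 0)

    def test_survival_frequency_matches_binomial(self):
        # 1e5 adults over one interval at phi = 0.73
        mu = float(logit(0.73))
        cfg = SimulationConfig(
            mu_ad=mu,
            sigma_ad=0.0,
            sigma_juv=0.0,
            rho=0.0,
            T=2,
            releases_per_occasion=100_000,
            juvenile_fraction=0.0,
        )
        rates = draw_annual_rates(cfg, seed=0)
        z, tau, _ = simulate_latent_states(rates, cfg, seed=1)
        first_cohort = tau == 0
        frac = z[first_cohort, 1].mean()
        assert abs(frac - 0.73) < 0.005


class TestDetections:
    def test_perfect_detection_reveals_latent_states(self):
        cfg = SimulationConfig(T=6, releases_per_occasion=30, rho=0.2)
        rates = draw_annual_rates(cfg, seed=0)
        z, tau, age = simulate_latent_states(rates, cfg, seed=1)
        hist = simulate_detections(z, 1.0, seed=2, tau=tau, age_at_release=age)
        cols = np.arange(6)
        after = cols[None, :] >= tau[:, None]
        assert np.array_equal(hist.y[after], z[after])

    def test_zero_detection_means_no_reencounters(self):
        cfg = SimulationConfig(T=6, releases_per_occasion=30, rho=0.2)
        rates = draw_annual_rates(cfg, seed=0)
        z, tau, age = simulate_latent_states(rates, cfg, seed=1)
        hist = simulate_detections(z, 0.0, seed=2, tau=tau, age_at_release=age)
        assert hist.y.sum() == len(tau)  # only the releases themselves

    def test_detection_frequency(self):
        # ~1e5 known-alive later occasions at p = 0.5
        cfg = SimulationConfig(T=2, releases_per_occasion=100_000, rho=0.0)
        z = np.ones((100_000, 2), dtype=np.int8)
        tau = np.zeros(100_000, dtype=np.int64)
        hist = simulate_detections(z, 0.5, seed=3, tau=tau)
        frac = hist.y[:, 1].mean()
        assert abs(frac - 0.5) < 0.005


class TestSimulateDataset:
    def test_reproducible_bytes(self):
        cfg = SimulationConfig(T=10, releases_per_occasion=100, seed=77)
        h1, r1 = simulate_dataset(cfg)
        h2, r2 = simulate_dataset(cfg)
        assert np.array_equal(h1.y, h2.y)
        assert np.array_equal(h1.tau, h2.tau)
        assert np.array_equal(h1.age_at_release, h2.age_at_release)
        assert r1.rho_true == r2.rho_true

    def test_total_individuals(self):
        cfg = SimulationConfig(T=10, releases_per_occasion=100, rho=0.1, seed=1)
        hist, _ = simulate_dataset(cfg)
        assert hist.n_individuals == 10 * 100

    def test_no_detection_outside_window(self):
        cfg = SimulationConfig(T=7, releases_per_occasion=60, rho=-0.4, seed=2)
        hist, _ = simulate_dataset(cfg)
        cols = np.arange(7)
        before = cols[None, :] < hist.tau[:, None]
        assert hist.y[before].sum() == 0

    def test_detections_subset_of_alive(self):
        cfg = SimulationConfig(T=7, releases_per_occasion=60, rho=0.4, seed=3)
        hist, _ = simulate_dataset(cfg)
        cols = np.arange(7)
        after = cols[None, :] > hist.tau[:, None]
        assert np.all(hist.y[after] <= hist.z[after])

    def test_marray_frequencies_match_multinomial_cells(self):
        """At T = 3 with constant rates the m-array cell frequencies must sit
        within 3 Monte Carlo SEs of the analytic multinomial probabilities."""
        from procjs import build_marrays

        phi_ad, phi_juv, p = expit(1.0), expit(-1.0), 0.5
        cfg = SimulationConfig(
            sigma_ad=0.0,
            sigma_juv=0.0,
            rho=0.0,
            T=3,
            releases_per_occasion=5000,
            seed=11,
        )
        hist, _ = simulate_dataset(cfg)
        marr = build_marrays(hist)
        # adult row released at occasion 0 (hand-derived cell probabilities)
        expected = np.array(
            [phi_ad * p, phi_ad * (1 - p) * phi_ad * p, 0.0]
        )
        expected[2] = 1.0 - expected[:2].sum()
        row = marr.m_ad[0]
        n = row.sum()
        frac = row / n
        se = np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(frac - expected) <= 3 * se + 1e-12)
        # juvenile row: first interval uses juvenile survival
        expected_j = np.array(
            [phi_juv * p, phi_juv * (1 - p) * phi_ad * p, 0.0]
        )
        expected_j[2] = 1.0 - expected_j[:2].sum()
        row_j = marr.m_juv[0]
        frac_j = row_j / row_j.sum()
        se_j = np.sqrt(expected_j * (1 - expected_j) / row_j.sum())
        assert np.all(np.abs(frac_j - expected_j) <= 3 * se_j + 1e-12)


class TestEncounterHistoryValidation:
    def test_detection_before_release_rejected(self):
        y = np.array([[1, 1, 0], [1, 0, 0]], dtype=np.int8)
        tau = np.array([1, 0])
        age = np.array([1, 1], dtype=np.int8)
        with pytest.raises(ValueError, match="before its release"):
            EncounterHistorySet(y=y, tau=tau, age_at_release=age)

    def test_release_must_be_encounter(self):
        y = np.array([[0, 1, 0]], dtype=np.int8)
        with pytest.raises(ValueError, match="not marked detected"):
            EncounterHistorySet(
                y=y, tau=np.array([0]), age_at_release=np.array([1], dtype=np.int8)
            )

    def test_config_validation(self):
        with pytest.raises(ValueError, match="T"):
            SimulationConfig(T=1)
        with pytest.raises(ValueError, match="rho"):
            SimulationConfig(rho=1.5)
        with pytest.raises(ValueError, match="p"):
            SimulationConfig(p=0.0)
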