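"""Exact O-U transition mathematics against closed forms and brute force."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm, solve_continuous_lyapunov
from scipy.stats import multivariate_normal

import ougaze as og
from ougaze.exceptions import ContractError, ValidationError


def random_spd(rng, scale=1.0):
    A = rng.normal(0, scale, (2, 2))
    M = A @ A.T + 0.05 * scale**2 * np.eye(2)
    return M


def random_params(rng):
    return og.OUParams(random_spd(rng), random_spd(rng), rng.normal(0, 100, 2))


class TestStationaryCovariance:
    def test_diagonal_closed_form(self):
        # scalar reduction: D = Gamma^2 / (2 B) per component
        p = og.OUParams(np.diag([1.0, 2.0]), np.eye(2))
        assert np.allclose(og.stationary_covariance(p), np.diag([0.5, 0.25]), atol=1e-14)
        p = og.OUParams(np.eye(2), np.eye(2))
        assert np.allclose(og.stationary_covariance(p), 0.5 * np.eye(2), atol=1e-14)

    def test_lyapunov_residual_random_spd(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            p = random_params(rng)
            D = og.stationary_covariance(p)
            resid = p.B @ D + D @ p.B.T - p.Gamma @ p.Gamma
            assert np.linalg.norm(resid) < 1e-10
            assert np.linalg.eigvalsh(D).min() >= -1e-12

    def test_rejects_non_spd_drift(self):
        with pytest.raises(ValidationError):
            og.OUParams(np.diag([-1.0, 1.0]), np.eye(2))


class TestTransitionMoments:
    def test_zero_step_is_identity(self):
        p = og.OUParams(np.diag([0.3, 0.7]), np.eye(2), mu=[10.0, 20.0])
        m = og.transition_moments(p, [3.0, 4.0], 0.0)
        assert np.allclose(m.mean, [3.0, 4.0], atol=1e-14)
        assert np.allclose(m.cov_psi, 0.0, atol=1e-12)

    def test_unit_matrices_closed_form(self):
        p = og.OUParams(np.eye(2), np.eye(2))
        m = og.transition_moments(p, [1.0, 1.0], 1.0)
        assert np.allclose(m.mean, np.exp(-1.0), atol=1e-12)
        assert np.allclose(m.cov_psi, 0.5 * (1 - np.exp(-2.0)) * np.eye(2), atol=1e-12)

    def test_long_horizon_reaches_stationarity(self):
        p = og.OUParams(np.eye(2), np.diag([1.0, 2.0]), mu=[5.0, -3.0])
        m = og.transition_moments(p, [100.0, 100.0], 50.0)
        assert np.allclose(m.mean, p.mu, atol=1e-9)
        assert np.allclose(m.cov_psi, og.stationary_covariance(p), atol=1e-9)

    def test_matches_matrix_exponential_route(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = random_params(rng)
            x = rng.normal(0, 50, 2)
            dt = rng.uniform(0.1, 5.0)
            m = og.transition_moments(p, x, dt)
            E = expm(-p.B * dt)
            D = solve_continuous_lyapunov(p.B, p.Gamma @ p.Gamma)
            assert np.allclose(m.mean, p.mu + E @ (x - p.mu), atol=1e-10)
            assert np.allclose(m.cov_psi, D - E @ D @ E.T, atol=1e-9)

    def test_psi_loewner_monotone_in_dt(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            p = random_params(rng)
            x = np.zeros(2)
            grid = [0.0, 0.2, 0.5, 1.0, 2.0, 5.0, 20.0]
            prev = og.transition_moments(p, x, grid[0]).cov_psi
            for dt in grid[1:]:
                cur = og.transition_moments(p, x, dt).cov_psi
                assert np.linalg.eigvalsh(cur - prev).min() >= -1e-9
                prev = cur
            # Psi(inf) = stationary covariance bounds the chain from above
            D = og.stationary_covariance(p)
            assert np.linalg.eigvalsh(D - prev).min() >= -1e-9

    def test_negative_dt_rejected(self):
        p = og.OUParams(np.eye(2), np.eye(2))
        with pytest.raises(ContractError):
            og.transition_moments(p, [0.0, 0.0], -1.0)


class TestSampleTransition:
    def test_noise_free_limit_returns_mean(self):
        m = og.TransitionMoments([3.0, 4.0], 1e-12 * np.eye(2))
        draw = og.sample_transition(m, np.random.default_rng(0))
        assert np.allclose(draw, [3.0, 4.0], atol=1e-5)

    def test_seed_determinism(self):
        m = og.TransitionMoments([0.0, 0.0], np.array([[2.0, 0.5], [0.5, 1.0]]))
        a = og.sample_transition(m, np.random.default_rng(123))
        b = og.sample_transition(m, np.random.default_rng(123))
        assert np.array_equal(a, b)

    def test_moments_match_analytic_within_mc_error(self):
        p = og.OUParams(
            np.array([[0.4, 0.1], [0.1, 0.6]]),
            np.array([[1.5, 0.3], [0.3, 1.0]]),
            mu=[100.0, 200.0],
        )
        m = og.transition_moments(p, [90.0, 195.0], 1.0)
        rng = np.random.default_rng(2024)
        draws = np.array([og.sample_transition(m, rng) for _ in range(20_000)])
        n = len(draws)
        se_mean = np.sqrt(np.diag(m.cov_psi) / n)
        assert np.all(np.abs(draws.mean(axis=0) - m.mean) < 4 * se_mean)
        emp_cov = np.cov(draws.T)
        for i in range(2):
            for j in range(2):
                se = np.sqrt(
                    (m.cov_psi[i, i] * m.cov_psi[j, j] + m.cov_psi[i, j] ** 2) / n
                )
                assert abs(emp_cov[i, j] - m.cov_psi[i, j]) < 4 * se

    def test_agrees_with_euler_maruyama_substeps(self):
        # fine Euler-Maruyama integration of the SDE over one unit step
        p = og.OUParams(np.diag([0.5, 0.8]), np.diag([1.0, 1.5]), mu=[10.0, -5.0])
        x0 = np.array([0.0, 0.0])
        m = og.transition_moments(p, x0, 1.0)
        rng = np.random.default_rng(8)
        h, n_sub, n_rep = 0.01, 100, 5000
        finals = np.empty((n_rep, 2))
        for r in range(n_rep):
            x = x0.copy()
            for _ in range(n_sub):
                x = x + p.B @ (p.mu - x) * h + p.Gamma @ rng.normal(0, np.sqrt(h), 2)
            finals[r] = x
        se = np.sqrt(np.diag(m.cov_psi) / n_rep)
        assert np.all(np.abs(finals.mean(axis=0) - m.mean) < 4 * se + 0.02)
        assert np.allclose(np.cov(finals.T), m.cov_psi, rtol=0.15, atol=0.02)


class TestEventLogLikelihood:
    def test_two_sample_slice_is_single_density(self):
        p = og.OUParams(np.diag([0.3, 0.3]), np.eye(2), mu=[1.0, 1.0])
        x = np.array([[0.0, 0.0], [0.5, 0.2]])
        m = og.transition_moments(p, x[0], 1.0)
        expected = multivariate_normal(m.mean, m.cov_psi).logpdf(x[1])
        assert og.event_log_likelihood(x, p) == pytest.approx(expected, abs=1e-10)

    def test_matches_naive_per_step_loop(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            p = random_params(rng)
            x = og.simulate_event(p, p.mu + rng.normal(0, 5, 2), 50, rng)
            naive = sum(
                multivariate_normal(
                    (mm := og.transition_moments(p, x[i], 1.0)).mean, mm.cov_psi
                ).logpdf(x[i + 1])
                for i in range(len(x) - 1)
            )
            assert og.event_log_likelihood(x, p) == pytest.approx(naive, abs=1e-10)

    def test_true_parameters_beat_misspecified_drift(self):
        rng = np.random.default_rng(17)
        p = og.OUParams(np.diag([0.1, 0.1]), np.eye(2))
        x = og.simulate_event(p, [3.0, -3.0], 5000, rng)
        wrong = og.OUParams(2 * p.B, p.Gamma, p.mu)
        assert og.event_log_likelihood(x, p) > og.event_log_likelihood(x, wrong)

    def test_short_slice_rejected(self):
        p = og.OUParams(np.eye(2), np.eye(2))
        with pytest.raises(ContractError):
            og.event_log_likelihood(np.zeros((1, 2)), p)

    def test_diagonal_inputs_decouple_dimensions(self):
        # diagonal B, Gamma = two independent 1-D processes
        p = og.OUParams(np.diag([0.2, 0.4]), np.diag([1.0, 2.0]))
        rng = np.random.default_rng(21)
        x = og.simulate_event(p, [0.0, 0.0], 20_000, rng)
        r = x[1:] - x[:-1] * np.exp(-np.diag(p.B))
        cross = np.corrcoef(r.T)[0, 1]
        assert abs(cross) < 0.03
        assert np.allclose(og.transition_moments(p, [1.0, 1.0], 1.0).cov_psi[0, 1], 0.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_transition_mean_contracts_toward_attractor(seed):
    """The conditional mean always lies between the state and the attractor."""
    rng = np.random.default_rng(seed)
    p = random_params(rng)
    x = rng.normal(0, 100, 2)
    m = og.transition_moments(p, x, rng.uniform(0.0, 10.0))
    # e^{-B dt} is a contraction for SPD B: ||mean - mu|| <= ||x - mu||
    assert np.linalg.norm(m.mean - p.mu) <= np.linalg.norm(x - p.mu) + 1e-9
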