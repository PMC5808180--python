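"""Matrix-variate normal MLE: mean, covariance fixed point, likelihood."""

import math

import numpy as np
import pytest

from mvndfc import (
    EstimatorConfig,
    TimeSeriesMatrix,
    WindowConfig,
    estimate_mean,
    estimate_omega,
    fit_mvnd,
    neg_log_likelihood,
    normalize_to_correlation,
    omega_free_parameters,
    omega_update,
    pearson_network,
    sample_matrix_normal,
    sigma_free_parameters,
    window_network_series,
)
from mvndfc.exceptions import (
    EmptySampleList,
    InsufficientWindows,
    NonPositiveDefiniteOmega,
    NonPositiveDiagonal,
    ShapeMismatch,
    SingularOmega,
)


def omega_update_oracle(samples, m, omega):
    """Naive triple-loop evaluation of the covariance fixed-point step."""
    k = len(samples)
    p = m.shape[0]
    inv = np.linalg.inv(omega)
    out = np.zeros((p, p))
    for w in samples:
        s = w - m
        for a in range(p):
            for b in range(p):
                acc = 0.0
                for u in range(p):
                    for t in range(p):
                        acc += s[a, u] * inv[u, t] * s[b, t]
                out[a, b] += acc
    return out / (k * p)


def normalized(a):
    d = np.sqrt(np.diag(a))
    return a / np.outer(d, d)


class TestEstimateMean:
    def test_symmetric_pair_averages_to_identity(self):
        s1 = np.array([[1.0, 0.5], [0.5, 1.0]])
        s2 = np.array([[1.0, -0.5], [-0.5, 1.0]])
        np.testing.assert_array_equal(estimate_mean([s1, s2]), np.eye(2))

    def test_single_sample_unchanged(self, rng):
        w = rng.standard_normal((4, 4))
        np.testing.assert_array_equal(estimate_mean([w]), w)

    def test_matches_accumulation_loop(self, rng):
        samples = [rng.standard_normal((5, 5)) for _ in range(7)]
        acc = np.zeros((5, 5))
        for w in samples:
            for i in range(5):
                for j in range(5):
                    acc[i, j] += w[i, j]
        np.testing.assert_allclose(estimate_mean(samples), acc / 7, atol=1e-12)

    def test_errors(self, rng):
        with pytest.raises(EmptySampleList):
            estimate_mean([])
        with pytest.raises(ShapeMismatch):
            estimate_mean([np.eye(3), np.eye(4)])


class TestOmegaUpdate:
    def test_analytic_half_identity(self):
        samples = [np.eye(2), -np.eye(2)]
        out = omega_update(samples, np.zeros((2, 2)), np.eye(2))
        np.testing.assert_allclose(out, 0.5 * np.eye(2), atol=1e-14)

    def test_zero_residuals_give_zero_matrix(self, rng):
        m = rng.standard_normal((3, 3))
        out = omega_update([m, m, m], m, np.eye(3))
        np.testing.assert_array_equal(out, np.zeros((3, 3)))

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(20):
            samples = [rng.standard_normal((4, 4)) for _ in range(3)]
            m = rng.standard_normal((4, 4))
            a = rng.standard_normal((4, 4))
            omega = a @ a.T + 4 * np.eye(4)
            np.testing.assert_allclose(
                omega_update(samples, m, omega),
                omega_update_oracle(samples, m, omega),
                atol=1e-10,
            )

    def test_singular_omega_raises_with_condition(self):
        samples = [np.eye(2)]
        with pytest.raises(SingularOmega) as exc:
            omega_update(samples, np.zeros((2, 2)), np.zeros((2, 2)))
        assert exc.value.cond == math.inf or exc.value.cond > 1e12


class TestEstimateOmega:
    def test_analytic_fixed_point(self):
        samples = [np.eye(2), -np.eye(2)]
        omega, diag = estimate_omega(samples, np.zeros((2, 2)))
        assert diag.converged
        np.testing.assert_allclose(omega, np.eye(2) / math.sqrt(2), atol=1e-6)

    def test_degenerate_residuals_raise(self, rng):
        m = rng.standard_normal((3, 3))
        with pytest.raises(SingularOmega):
            estimate_omega([m, m, m], m)

    def test_monte_carlo_consistency(self):
        # At K=2000 draws the sampling error of the normalized factor is
        # comfortably below 0.1 (it scales as 1/sqrt(K), sitting right at
        # 0.1 for K around 500, too close to call for a fixed draw).
        rng = np.random.default_rng(123)
        p = 8
        a = rng.standard_normal((p, p))
        omega0 = a @ a.T / p + 0.5 * np.eye(p)
        m0 = 0.4 ** np.abs(np.subtract.outer(np.arange(p), np.arange(p))).astype(float)
        samples = sample_matrix_normal(m0, omega0, k=2000, seed=99)
        m_hat = estimate_mean(samples)
        omega_hat, diag = estimate_omega(samples, m_hat)
        assert diag.converged
        err = np.linalg.norm(normalized(omega_hat) - normalized(omega0))
        assert err < 0.1

    def test_recovery_improves_with_sample_size(self):
        rng = np.random.default_rng(7)
        p = 8
        a = rng.standard_normal((p, p))
        omega0 = a @ a.T / p + 0.5 * np.eye(p)
        m0 = 0.4 ** np.abs(np.subtract.outer(np.arange(p), np.arange(p))).astype(float)
        m_errs, o_errs = [], []
        for k in (50, 200, 800):
            samples = sample_matrix_normal(m0, omega0, k=k, seed=1000 + k)
            m_hat = estimate_mean(samples)
            omega_hat, _ = estimate_omega(samples, m_hat)
            m_errs.append(np.linalg.norm(m_hat - m0))
            o_errs.append(np.linalg.norm(normalized(omega_hat) - normalized(omega0)))
        assert m_errs[0] > m_errs[1] > m_errs[2]
        assert o_errs[0] > o_errs[1] > o_errs[2]

    def test_fixed_point_and_monotone_likelihood(self, rng):
        x = TimeSeriesMatrix(rng.standard_normal((80, 5)))
        cfg = WindowConfig(30, 10)
        nets = window_network_series(x, cfg)
        m = estimate_mean(nets)
        ecfg = EstimatorConfig(tol=1e-8, max_iter=400)
        omega, diag = estimate_omega(nets, m, ecfg)
        assert diag.converged
        residual = np.linalg.norm(omega_update(nets, m, omega) - omega)
        assert residual < ecfg.tol
        deltas = np.diff(diag.nll_trace)
        assert (deltas <= 1e-8).all()

    def test_scale_rigidity_of_fixed_point(self, rng):
        x = TimeSeriesMatrix(rng.standard_normal((80, 5)))
        nets = window_network_series(x, WindowConfig(30, 10))
        m = estimate_mean(nets)
        omega, _ = estimate_omega(nets, m, EstimatorConfig(tol=1e-10))
        for c in (2.0, 0.5):
            moved = np.linalg.norm(omega_update(nets, m, c * omega) - c * omega)
            assert moved > 1e-2  # c·Omega* is not a fixed point for c != 1


class TestNegLogLikelihood:
    def test_univariate_at_mean(self):
        value = neg_log_likelihood([np.zeros((1, 1))], np.zeros((1, 1)), np.eye(1))
        assert value == pytest.approx(0.5 * math.log(2 * math.pi), abs=1e-12)

    def test_univariate_one_sigma_away(self):
        value = neg_log_likelihood([np.ones((1, 1))], np.zeros((1, 1)), np.eye(1))
        assert value == pytest.approx(0.5 * math.log(2 * math.pi) + 0.5, abs=1e-12)

    def test_zero_residual_sample_adds_only_constants(self, rng):
        p = 3
        a = rng.standard_normal((p, p))
        omega = a @ a.T + p * np.eye(p)
        m = rng.standard_normal((p, p))
        samples = [m + rng.standard_normal((p, p)) for _ in range(4)]
        base = neg_log_likelihood(samples, m, omega)
        extended = neg_log_likelihood(samples + [m.copy()], m, omega)
        logdet = np.linalg.slogdet(omega)[1]
        expected_gain = 0.5 * p * p * math.log(2 * math.pi) + p * logdet
        assert extended - base == pytest.approx(expected_gain, rel=1e-10)

    def test_indefinite_omega_raises(self):
        with pytest.raises(NonPositiveDefiniteOmega):
            neg_log_likelihood([np.eye(2)], np.zeros((2, 2)), -np.eye(2))


class TestNormalizeToCorrelation:
    def test_example(self):
        out = normalize_to_correlation(np.array([[4.0, 2.0], [2.0, 9.0]]))
        np.testing.assert_allclose(out.values, [[1, 1 / 3], [1 / 3, 1]], atol=1e-12)

    def test_identity_and_scale_invariance(self, rng):
        a = rng.standard_normal((4, 4))
        omega = a @ a.T + np.eye(4)
        np.testing.assert_array_equal(normalize_to_correlation(np.eye(3)).values, np.eye(3))
        np.testing.assert_allclose(
            normalize_to_correlation(3.7 * omega).values,
            normalize_to_correlation(omega).values,
            atol=1e-12,
        )

    def test_nonpositive_diagonal_raises_with_index(self):
        with pytest.raises(NonPositiveDiagonal) as exc:
            normalize_to_correlation(np.diag([1.0, 0.0, 2.0]))
        assert exc.value.index == 1


class TestFitMvnd:
    def test_mean_approaches_full_series_network(self, stationary_series):
        # As the window width approaches the series length, every window
        # shares most of its rows with the full series, so the windowed
        # mean M converges to the full-series Pearson network.
        x, _ = stationary_series
        full_pc = pearson_network(x).values
        errs = []
        for width in (120, 180, 230):
            est = fit_mvnd(x, WindowConfig(width, 5))
            errs.append(np.linalg.norm(est.M.values - full_pc))
        assert errs[0] > errs[1] > errs[2]
        assert errs[-1] < 0.1

    def test_single_window_raises(self, rng):
        x = TimeSeriesMatrix(rng.standard_normal((20, 4)))
        with pytest.raises(InsufficientWindows):
            fit_mvnd(x, WindowConfig(20, 5))

    def test_repeat_runs_bitwise_identical(self, rng):
        x = TimeSeriesMatrix(rng.standard_normal((70, 5)))
        cfg = WindowConfig(25, 5)
        first = fit_mvnd(x, cfg)
        second = fit_mvnd(x, cfg)
        np.testing.assert_array_equal(first.M.values, second.M.values)
        np.testing.assert_array_equal(first.Omega_raw, second.Omega_raw)
        np.testing.assert_array_equal(first.Omega.values, second.Omega.values)
        assert first.nll_trace == second.nll_trace

    def test_populates_diagnostics_and_kinds(self, rng):
        x = TimeSeriesMatrix(rng.standard_normal((70, 5)))
        est = fit_mvnd(x, WindowConfig(25, 5))
        assert est.M.kind == "low_order_M"
        assert est.Omega.kind == "high_order_Omega"
        assert est.n_iterations >= 1
        assert est.final_delta >= 0
        w = np.linalg.eigvalsh(0.5 * (est.Omega_raw + est.Omega_raw.T))
        assert w.min() > -1e-10


class TestParameterCounts:
    def test_kronecker_reduction_at_study_scale(self):
        assert sigma_free_parameters(116) == 90_525_240
        assert abs(sigma_free_parameters(116) - 9e7) / 9e7 < 0.01
        assert omega_free_parameters(116) == 116 * 115 // 2 == 6_670

    @pytest.mark.parametrize("p", [2, 3, 10])
    def test_formulas(self, p):
        assert sigma_free_parameters(p) == p * p * (p * p - 1) // 2
        assert omega_free_parameters(p) == p * (p - 1) // 2
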