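import numpy as np
import pytest

from fcdbn import ChangePointVector, Level2Hyper, log_marginal_likelihood
from fcdbn.regression import (
    CrossProductCache,
    sample_delta_inv,
    sample_sigma2_inv,
    sample_w,
    segment_quadratic_terms,
)


@pytest.fixture
def hyper():
    return Level2Hyper()


class TestMarginalLikelihood:
    def test_invariant_to_parent_ordering(self, small_dataset, hyper):
        V = ChangePointVector(small_dataset.n_times, (6,))
        a = log_marginal_likelihood(small_dataset, 1, [0, 2], V, 0.7, hyper)
        b = log_marginal_likelihood(small_dataset, 1, [2, 0], V, 0.7, hyper)
        assert a == pytest.approx(b, rel=1e-12)

    def test_matches_explicit_dense_linear_algebra(self, small_dataset, hyper):
        """Cholesky/Woodbury path equals the naive full-matrix computation."""
        from scipy.special import gammaln

        from fcdbn import build_design

        V = ChangePointVector(small_dataset.n_times, (5,))
        delta = 0.9
        g, parents = 1, (0, 2)
        logdet, quad = 0.0, 0.0
        for lo, hi in V.segments():
            y, X = build_design(small_dataset, g, parents, range(lo, hi + 1))
            Sigma = np.eye(len(y)) + delta * X @ X.T
            sign, ld = np.linalg.slogdet(Sigma)
            logdet += ld
            quad += y @ np.linalg.solve(Sigma, y)
        n = small_dataset.n_times - 1
        A, B = hyper.A_sigma, hyper.B_sigma
        expected = (
            -0.5 * logdet
            + A * np.log(B)
            - (A + n / 2) * np.log(B + quad / 2)
            + gammaln(A + n / 2)
            - gammaln(A)
            - n / 2 * np.log(2 * np.pi)
        )
        got = log_marginal_likelihood(small_dataset, g, parents, V, delta, hyper)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_zero_response_leaves_only_logdet_terms(self, hyper):
        """With y identically 0 the quadratic terms vanish, so splitting the
        segments changes only the log-determinant contributions."""
        from fcdbn import TimeSeriesDataset

        rng = np.random.default_rng(0)
        v = rng.standard_normal((2, 12))
        v[0] = 0.0  # target gene: zero response
        data = TimeSeriesDataset(v, ("z", "p"))
        one = ChangePointVector(12)
        two = ChangePointVector(12, (7,))
        ld1, q1 = segment_quadratic_terms(data, 0, (1,), one, 1.0, None)
        ld2, q2 = segment_quadratic_terms(data, 0, (1,), two, 1.0, None)
        assert q1 == pytest.approx(0.0, abs=1e-12)
        assert q2 == pytest.approx(0.0, abs=1e-12)
        diff = log_marginal_likelihood(data, 0, (1,), two, 1.0, hyper) - (
            log_marginal_likelihood(data, 0, (1,), one, 1.0, hyper)
        )
        assert diff == pytest.approx(-0.5 * (ld2 - ld1))

    def test_segment_additivity_of_quadratic_terms(self, small_dataset):
        """Per-segment log-dets and quadratic forms add; segmentation couples
        genes only through the final shared rate term."""
        V = ChangePointVector(small_dataset.n_times, (6,))
        ld, q = segment_quadratic_terms(small_dataset, 0, (1,), V, 0.5, None)
        cache = CrossProductCache(small_dataset)
        cols = np.array([0, 2])
        acc_ld = acc_q = 0.0
        from fcdbn.regression import _logdet_and_quad

        for lo, hi in V.segments():
            st = cache.segment_stats(0, cols, lo, hi)
            l, qq = _logdet_and_quad(st, 0.5)
            acc_ld += l
            acc_q += qq
        assert ld == pytest.approx(acc_ld)
        assert q == pytest.approx(acc_q)

    def test_nonpositive_delta_rejected(self, small_dataset, hyper):
        V = ChangePointVector(small_dataset.n_times)
        with pytest.raises(ValueError):
            log_marginal_likelihood(small_dataset, 0, (), V, 0.0, hyper)


class TestCoefficientSampling:
    def test_zero_design_recovers_prior(self, rng):
        """X = 0 gives posterior mean 0 and covariance sigma2 * delta * I."""
        X = np.zeros((6, 2))
        y = np.zeros(6)
        delta, sigma2 = 2.0, 0.5
        draws = np.array([sample_w(y, X, delta, sigma2, rng) for _ in range(20_000)])
        np.testing.assert_allclose(draws.mean(axis=0), 0, atol=0.05)
        np.testing.assert_allclose(
            np.cov(draws.T), sigma2 * delta * np.eye(2), atol=0.05
        )

    def test_mean_matches_closed_form_ridge(self, rng):
        X = rng.standard_normal((30, 3))
        w_true = np.array([1.0, -0.5, 0.25])
        y = X @ w_true + 0.1 * rng.standard_normal(30)
        delta, sigma2 = 1.0, 0.01
        ridge = np.linalg.solve(np.eye(3) / delta + X.T @ X, X.T @ y)
        draws = np.array(
            [sample_w(y, X, delta, sigma2, rng) for _ in range(50_000)]
        )
        se = draws.std(axis=0) / np.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - ridge) < 3 * se + 1e-12)

    def test_zero_noise_limit_collapses_to_ridge(self, rng):
        X = rng.standard_normal((10, 2))
        y = rng.standard_normal(10)
        delta = 0.5
        ridge = np.linalg.solve(np.eye(2) / delta + X.T @ X, X.T @ y)
        draw = sample_w(y, X, delta, 1e-18, rng)
        np.testing.assert_allclose(draw, ridge, atol=1e-6)

    def test_nonfinite_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_w(np.array([np.inf, 0.0]), np.ones((2, 1)), 1.0, 1.0, rng)


class TestHyperparameterSampling:
    def test_delta_inv_shape_rate_arithmetic(self, rng):
        """K=1, two coefficients w=(1,1), sigma2=1, A=B=2 -> Gamma(3, 3)."""
        hyper = Level2Hyper(A_delta=2.0, B_delta=2.0)
        draws = np.array(
            [
                sample_delta_inv([np.array([1.0, 1.0])], 1.0, hyper, rng)
                for _ in range(100_000)
            ]
        )
        # shape 2 + 1*2/2 = 3, rate 2 + (1/2)*2 = 3 -> mean 1, var 1/3
        assert draws.mean() == pytest.approx(1.0, abs=0.02)
        assert draws.var() == pytest.approx(1 / 3, abs=0.02)

    def test_delta_inv_prior_recovery_with_zero_coefficients(self, rng):
        hyper = Level2Hyper(A_delta=3.0, B_delta=1.5)
        draws = np.array(
            [
                sample_delta_inv([np.zeros(2), np.zeros(2)], 1.0, hyper, rng)
                for _ in range(100_000)
            ]
        )
        shape, rate = 3.0 + 2 * 2 / 2, 1.5
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - shape / rate) < 3 * se

    def test_delta_inv_empty_w_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_delta_inv([], 1.0, Level2Hyper(), rng)

    def test_sigma2_inv_rate_matches_explicit_inversion(self, small_dataset, rng):
        from fcdbn import build_design

        V = ChangePointVector(small_dataset.n_times, (6,))
        delta = 1.3
        quad = 0.0
        for lo, hi in V.segments():
            y, X = build_design(small_dataset, 1, (0,), range(lo, hi + 1))
            quad += y @ np.linalg.inv(np.eye(len(y)) + delta * X @ X.T) @ y
        hyper = Level2Hyper()
        n = small_dataset.n_times - 1
        shape, rate = hyper.A_sigma + n / 2, hyper.B_sigma + quad / 2
        draws = np.array(
            [
                sample_sigma2_inv(small_dataset, 1, (0,), V, delta, hyper, rng)
                for _ in range(50_000)
            ]
        )
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - shape / rate) < 3 * se

    def test_sigma2_inv_zero_response_is_prior(self, rng):
        from fcdbn import TimeSeriesDataset

        v = np.zeros((2, 8))
        v[1] = np.arange(8.0)
        data = TimeSeriesDataset(v, ("z", "p"))
        hyper = Level2Hyper(A_sigma=2.0, B_sigma=3.0)
        V = ChangePointVector(8)
        draws = np.array(
            [
                sample_sigma2_inv(data, 0, (), V, 1.0, hyper, rng)
                for _ in range(50_000)
            ]
        )
        shape, rate = 2.0 + 7 / 2, 3.0
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - shape / rate) < 3 * se


class TestGibbsConsistency:
    def test_gibbs_posterior_mean_matches_closed_form(self, small_dataset, rng):
        """Alternating w / delta / sigma draws on fixed (pi, V) concentrate on
        the closed-form conditional mean of w given the other parameters'
        posterior means."""
        from fcdbn import build_design

        V = ChangePointVector(small_dataset.n_times)
        y, X = build_design(small_dataset, 1, (0,), range(2, small_dataset.n_times + 1))
        hyper = Level2Hyper()
        delta_inv, sigma2_inv = 1.0, 1.0
        ws, deltas, sigmas = [], [], []
        for _ in range(4000):
            sigma2_inv = sample_sigma2_inv(
                small_dataset, 1, (0,), V, 1 / delta_inv, hyper, rng
            )
            w = sample_w(y, X, 1 / delta_inv, 1 / sigma2_inv, rng)
            delta_inv = sample_delta_inv([w], 1 / sigma2_inv, hyper, rng)
            ws.append(w)
            deltas.append(delta_inv)
            sigmas.append(sigma2_inv)
        w_bar = np.mean(ws[500:], axis=0)
        delta_bar = 1 / np.mean(deltas[500:])
        cond_mean = np.linalg.solve(np.eye(2) / delta_bar + X.T @ X, X.T @ y)
        np.testing.assert_allclose(w_bar, cond_mean, atol=0.1)
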