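"""Conjugate piecewise linear-Gaussian regression.

Each gene g follows a lag-1 regression y_g(t) = [1, parents(t-1)] . w_{g,k}
+ eps, with segment-specific coefficients w_{g,k} over the segments of a
change-point vector.  Priors are the standard conjugate hierarchy

    w_{g,k} | sigma_g^2, delta_g   ~  N(0, delta_g sigma_g^2 I)
    delta_g^-1                     ~  Gamma(A_delta, B_delta)
    sigma_g^-2                     ~  Gamma(A_sigma, B_sigma)

so that w and sigma^2 integrate out in closed form.  The collapsed marginal
likelihood returned by :func:`log_marginal_likelihood` is the quantity driving
both the structure and the change-point samplers:

    log P(y_g | X, delta_g) =
        -1/2 sum_k log det(I + delta X_k^T X_k)
        + A_s log B_s - (A_s + n/2) log(B_s + 1/2 sum_k q_k)
        + log Gamma(A_s + n/2) - log Gamma(A_s) - n/2 log 2 pi

with n = T - 1 response times, q_k = y_k^T (I + delta X_k X_k^T)^{-1} y_k
evaluated via the Woodbury identity, and Cholesky factorizations throughout
(no explicit inverses in the hot path).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import gammaln

from .data import ChangePointVector, Level2Hyper, TimeSeriesDataset

__all__ = [
    "SegmentSuffStats",
    "CrossProductCache",
    "log_marginal_likelihood",
    "segment_quadratic_terms",
    "sample_w",
    "sample_delta_inv",
    "sample_sigma2_inv",
]


@dataclass(frozen=True)
class SegmentSuffStats:
    """Sufficient statistics of one segment's design: X'X, X'y, y'y, n."""

    XtX: np.ndarray
    Xty: np.ndarray
    yty: float
    n: int


class CrossProductCache:
    """Prefix sums of lag-1 cross products for O(p^2) segment statistics.

    Row 0 of the augmented predictor matrix is the intercept; row p+1 is gene
    p at time t-1.  Because segments are contiguous response-time ranges,
    any segment's X'X / X'y / y'y follow from prefix-sum differences.
    """

    def __init__(self, data: TimeSeriesDataset):
        G, T = data.n_genes, data.n_times
        Z = np.vstack([np.ones(T - 1), data.values[:, : T - 1]])  # (G+1, T-1)
        Y = data.values[:, 1:]  # responses at t = 2..T
        outer = Z.T[:, :, None] * Z.T[:, None, :]  # (T-1, G+1, G+1)
        self._cumZZ = np.concatenate(
            [np.zeros((1, G + 1, G + 1)), np.cumsum(outer, axis=0)], axis=0
        )
        zy = Y.T[:, None, :] * Z.T[:, :, None]  # (T-1, G+1, G)
        self._cumZy = np.concatenate(
            [np.zeros((1, G + 1, G)), np.cumsum(zy, axis=0)], axis=0
        )
        self._cumyy = np.concatenate(
            [np.zeros((G, 1)), np.cumsum(Y * Y, axis=1)], axis=1
        )
        self.n_genes = G
        self.n_times = T

    def segment_stats(
        self, g: int, cols: np.ndarray, lo: int, hi: int
    ) -> SegmentSuffStats:
        """Statistics for gene g on response times lo..hi (inclusive).

        ``cols`` indexes the augmented predictor rows (0 = intercept,
        p + 1 = parent p) in design-column order.
        """
        a, b = lo - 2, hi - 1  # prefix indices: rows lo-2 .. hi-2
        dZZ = self._cumZZ[b] - self._cumZZ[a]
        XtX = dZZ[cols][:, cols]
        dZy = self._cumZy[b] - self._cumZy[a]
        Xty = dZy[cols, g]
        yty = float(self._cumyy[g, b] - self._cumyy[g, a])
        return SegmentSuffStats(XtX, Xty, yty, hi - lo + 1)


def _parent_cols(parents) -> np.ndarray:
    return np.asarray([0, *sorted(int(p) + 1 for p in parents)], dtype=int)


def _segment_stats_list(data, g, parents, V, cache):
    if cache is None:
        cache = CrossProductCache(data)
    cols = _parent_cols(parents)
    return [cache.segment_stats(g, cols, lo, hi) for lo, hi in V.segments()]


def _logdet_and_quad(stats: SegmentSuffStats, delta: float) -> tuple[float, float]:
    p = stats.XtX.shape[0]
    A = np.eye(p) + delta * stats.XtX
    try:
        L = np.linalg.cholesky(A)
    except np.linalg.LinAlgError as exc:  # cannot occur for delta > 0; guard
        raise ValueError("numerically singular I + delta X'X") from exc
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    # Woodbury: y'(I_n + d XX')^{-1} y = y'y - d (X'y)' (I_p + d X'X)^{-1} X'y
    u = solve_triangular(L, stats.Xty, lower=True, check_finite=False)
    quad = stats.yty - delta * float(u @ u)
    return logdet, quad


def segment_quadratic_terms(
    data: TimeSeriesDataset,
    g: int,
    parents,
    V: ChangePointVector,
    delta: float,
    cache: CrossProductCache | None = None,
) -> tuple[float, float]:
    """Return (sum of log dets, sum of quadratic forms) over segments."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    logdet_sum = 0.0
    quad_sum = 0.0
    for st in _segment_stats_list(data, g, parents, V, cache):
        ld, q = _logdet_and_quad(st, delta)
        logdet_sum += ld
        quad_sum += q
    return logdet_sum, quad_sum


def log_marginal_likelihood(
    data: TimeSeriesDataset,
    g: int,
    parents,
    V: ChangePointVector,
    delta: float,
    hyper: Level2Hyper,
    cache: CrossProductCache | None = None,
) -> float:
    """Collapsed log marginal P(y_g | X, delta) with w and sigma^2 integrated out.

    Invariant to the ordering of ``parents``; finite for all valid inputs.
    """
    logdet_sum, quad_sum = segment_quadratic_terms(data, g, parents, V, delta, cache)
    n = data.n_times - 1
    A_s, B_s = hyper.A_sigma, hyper.B_sigma
    return (
        -0.5 * logdet_sum
        + A_s * np.log(B_s)
        - (A_s + n / 2) * np.log(B_s + 0.5 * quad_sum)
        + gammaln(A_s + n / 2)
        - gammaln(A_s)
        - (n / 2) * np.log(2 * np.pi)
    )


def sample_w(
    y: np.ndarray,
    X: np.ndarray,
    delta: float,
    sigma2: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw segment coefficients from their Gaussian full conditional.

    Posterior: N((delta^-1 I + X'X)^{-1} X'y, sigma^2 (delta^-1 I + X'X)^{-1}).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if delta <= 0 or sigma2 <= 0:
        raise ValueError("delta and sigma2 must be positive")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(X))):
        raise ValueError("non-finite inputs")
    p = X.shape[1]
    M = np.eye(p) / delta + X.T @ X
    c, low = cho_factor(M, lower=True)
    mean = cho_solve((c, low), X.T @ y)
    # M = L L' => cov = s2 M^{-1}; draw mean + sqrt(s2) L'^{-T} z
    z = rng.standard_normal(p)
    return mean + np.sqrt(sigma2) * solve_triangular(c, z, lower=True, trans="T")


def sample_delta_inv(
    w_all_segments: list[np.ndarray],
    sigma2: float,
    hyper: Level2Hyper,
    rng: np.random.Generator,
) -> float:
    """Draw delta^-1 from Gamma(A_d + K p / 2, B_d + sum_k w_k'w_k / (2 sigma^2))."""
    if not w_all_segments:
        raise ValueError("need at least one segment coefficient vector")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    K = len(w_all_segments)
    p = len(w_all_segments[0])
    shape = hyper.A_delta + K * p / 2
    rate = hyper.B_delta + sum(float(w @ w) for w in w_all_segments) / (2 * sigma2)
    return float(rng.gamma(shape, 1.0 / rate))


def sample_sigma2_inv(
    data: TimeSeriesDataset,
    g: int,
    parents,
    V: ChangePointVector,
    delta: float,
    hyper: Level2Hyper,
    rng: np.random.Generator,
    cache: CrossProductCache | None = None,
    quad_sum: float | None = None,
) -> float:
    """Draw sigma^-2 from its collapsed conditional (w integrated out).

    Gamma with shape A_s + (T-1)/2 and rate
    B_s + 1/2 sum_k y_k' (I + delta X_k X_k')^{-1} y_k.  A precomputed
    ``quad_sum`` may be supplied to avoid recomputation.
    """
    if quad_sum is None:
        _, quad_sum = segment_quadratic_terms(data, g, parents, V, delta, cache)
    n = data.n_times - 1
    shape = hyper.A_sigma + n / 2
    rate = hyper.B_sigma + 0.5 * quad_sum
    return float(rng.gamma(shape, 1.0 / rate))
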