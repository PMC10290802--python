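import numpy as np
import pytest

from fcdbn import ChangePointVector, TimeSeriesDataset
from fcdbn.changepoints import (
    _birth_location_probs,
    accept_changepoint,
    md_distance,
    move_rates,
    n_configurations,
    prior_log_pmf,
    propose_birth,
    propose_death,
    propose_shift,
)

CP_KW = dict(lam=1.0, lam_K=1.0, K_max=10, min_seg_len=2)


def shifted_series(T=20, tau=11, jump=2.0, seed=0):
    """Two-gene dataset whose first gene has a hard mean shift at time tau."""
    rng = np.random.default_rng(seed)
    x = 0.1 * rng.standard_normal((2, T))
    x[0, tau - 1 :] += jump
    return TimeSeriesDataset(x, ("a", "b"))


class TestMdDistance:
    def test_identical_segments_give_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert md_distance(x, x, 1.0) == 0.0

    def test_direct_arithmetic(self):
        # variances 0 and 0, means 0 and 1 -> d = 1
        assert md_distance(np.zeros(2), np.ones(2), 1.0) == pytest.approx(1.0)

    def test_linear_in_lambda(self, rng):
        a, b = rng.standard_normal(5), rng.standard_normal(5)
        assert md_distance(a, b, 2.0) == pytest.approx(2 * md_distance(a, b, 1.0))

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            md_distance(np.ones(1), np.ones(3), 1.0)


class TestMoveRates:
    @pytest.mark.parametrize("j", range(0, 6))
    def test_rates_sum_to_one_and_respect_truncation(self, j):
        b, d, r = move_rates(j, 1.0, K_max=6)
        assert b + d + r == pytest.approx(1.0)
        assert min(b, d, r) >= 0
        if j == 0:
            assert d == 0.0
        if j == 5:  # K = K_max
            assert b == 0.0

    def test_configuration_count_matches_enumeration(self):
        # T=10: 9 response times, j boundaries, segments >= 2
        for j in range(0, 4):
            count = 0
            from itertools import combinations

            for bs in combinations(range(3, 11), j):
                try:
                    V = ChangePointVector(10, bs)
                except ValueError:
                    continue
                if min(V.segment_lengths()) >= 2:
                    count += 1
            assert n_configurations(j, 10, 2) == count

    def test_prior_pmf_normalizes(self):
        total = sum(np.exp(prior_log_pmf(j, 1.0, 5)) for j in range(5))
        assert total == pytest.approx(1.0)


class TestBirth:
    def test_location_probabilities_normalize(self, rng):
        data = shifted_series()
        V = ChangePointVector(20)
        taus, probs = _birth_location_probs(V, data.values[0], 1.0, 2)
        assert probs.sum() == pytest.approx(1.0)
        assert taus == list(range(4, 20))  # both sub-segments >= 2

    def test_hard_shift_location_has_largest_probability(self, rng):
        # jump of 1.0: for a clean step the distance d is maximized exactly
        # at the step (larger jumps let mixture variance reward off-center
        # splits, since d sums the variance and mean differences)
        data = shifted_series(tau=11, jump=1.0)
        V = ChangePointVector(20)
        taus, probs = _birth_location_probs(V, data.values[0], 1.0, 2)
        assert taus[int(np.argmax(probs))] == 11

    def test_lambda_zero_is_uniform(self, rng):
        data = shifted_series()
        V = ChangePointVector(20)
        _, probs = _birth_location_probs(V, data.values[0], 0.0, 2)
        np.testing.assert_allclose(probs, 1 / len(probs))

    def test_probs_match_explicit_md_distance(self, rng):
        """Vectorized location weights equal exp(d(tau)) with d from the
        per-location Manhattan-distance computation."""
        data = shifted_series()
        V = ChangePointVector(20, (8,))
        x = data.values[0]
        taus, probs = _birth_location_probs(V, x, 1.3, 2)
        d = []
        for tau in taus:
            lo, hi = V.segments()[V.segment_of(tau)]
            d.append(md_distance(x[lo - 1 : tau - 1], x[tau - 1 : hi], 1.3))
        w = np.exp(np.array(d) - max(d))
        np.testing.assert_allclose(probs, w / w.sum(), rtol=1e-9)

    def test_no_admissible_location_returns_none(self, rng):
        data = shifted_series(T=5)
        V = ChangePointVector(5)  # 4 response times, min_seg_len 3
        mv = propose_birth(data=data, V=V, g=0, rng=rng,
                           lam=1.0, lam_K=1.0, K_max=10, min_seg_len=3)
        assert mv is None


class TestDeathAndShift:
    def test_single_boundary_deleted_with_certainty(self, rng):
        data = shifted_series()
        V = ChangePointVector(20, (11,))
        mv = propose_death(V, data, 0, rng=rng, **CP_KW)
        assert mv.position == 11
        assert mv.proposed.boundaries == ()

    def test_death_reverse_equals_birth_probability(self, rng):
        """q_reverse of deleting tau equals the MD-birth probability of
        re-proposing tau in the merged configuration, independently computed."""
        data = shifted_series()
        V = ChangePointVector(20, (7, 13))
        for _ in range(20):
            mv = propose_death(V, data, 0, rng=rng, **CP_KW)
            merged = mv.proposed
            taus, probs = _birth_location_probs(merged, data.values[0], 1.0, 2)
            b_prev, _, _ = move_rates(1, 1.0, 10)
            expected = b_prev * probs[taus.index(mv.position)]
            assert mv.q_reverse == pytest.approx(expected, rel=1e-12)

    def test_birth_then_death_restores_partition(self, rng):
        data = shifted_series()
        V = ChangePointVector(20, (9,))
        mv = propose_birth(V, data, 0, rng=rng, **CP_KW)
        removed = ChangePointVector(
            20, tuple(b for b in mv.proposed.boundaries if b != mv.position)
        )
        assert removed.boundaries == V.boundaries

    def test_shift_is_an_involution(self, rng):
        V = ChangePointVector(20, (10,))
        for _ in range(50):
            mv = propose_shift(V, min_seg_len=2, rng=rng)
            if mv is None:
                continue
            # one step away; stepping back restores the original partition
            step = mv.position - 10
            assert abs(step) == 1
            back = ChangePointVector(20, (mv.position - step,))
            assert back.boundaries == V.boundaries
            assert mv.q_forward == mv.q_reverse

    def test_shift_into_saturated_segment_rejected(self, rng):
        # boundary at 4: left segment is exactly min_seg_len=2 (times 2,3)
        V = ChangePointVector(8, (4,))
        lefts = 0
        for _ in range(200):
            mv = propose_shift(V, min_seg_len=2, rng=rng)
            if mv is not None and mv.position == 3:
                lefts += 1
        assert lefts == 0

    def test_shift_directions_balanced(self, rng):
        V = ChangePointVector(40, (20,))
        left = right = 0
        n = 20_000
        for _ in range(n):
            mv = propose_shift(V, min_seg_len=2, rng=rng)
            if mv.position < 20:
                left += 1
            else:
                right += 1
        assert abs(left / n - 0.5) < 3 * np.sqrt(0.25 / n)


class TestAcceptance:
    def test_symmetric_equal_score_shift_always_accepted(self, rng):
        V = ChangePointVector(20, (10,))
        for _ in range(50):
            mv = propose_shift(V, min_seg_len=2, rng=rng)
            if mv is not None:
                assert accept_changepoint(mv, -3.0, -3.0, rng)

    def test_nonfinite_score_rejected(self, rng):
        V = ChangePointVector(20, (10,))
        mv = propose_shift(V, min_seg_len=2, rng=rng)
        assert not accept_changepoint(mv, -3.0, -np.inf, rng)
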