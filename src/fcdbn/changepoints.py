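"""Reversible-jump MCMC over per-gene change-point vectors.

Three move kinds act on a gene's segmentation: a birth inserts a boundary, a
death removes one, and a shift slides a boundary one step.  The birth
location is not uniform: candidate position tau gets weight exp(d(tau)) with

    d(tau) = lam * (|var(left) - var(right)| + |mean(left) - mean(right)|)

the Manhattan distance between the would-be sub-segments' first two moments
of the gene's own series, so births are drawn toward positions where the
data actually change regime.  lam = 0 recovers the distance-blind uniform
birth.  Because the collapsed marginal likelihood integrates out all
segment-specific parameters, no Jacobian term appears in the acceptance
ratio — only the prior ratio (truncated Poisson on the number of change
points, uniform over admissible configurations given that number) and the
exact forward/reverse proposal probabilities.

Move-kind rates follow the standard schedule b_j = c min(1, p(j+1)/p(j)),
d_j = c min(1, p(j-1)/p(j)), r_j = 1 - b_j - d_j (c = 0.4), truncated at
j = 0 and at K_max segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, lgamma, log

import numpy as np

from .data import ChangePointVector, TimeSeriesDataset

__all__ = [
    "ChangePointMove",
    "md_distance",
    "move_rates",
    "n_configurations",
    "prior_log_pmf",
    "propose_birth",
    "propose_death",
    "propose_shift",
    "accept_changepoint",
]

_RATE_C = 0.4  # b + d <= 0.8, so the shift move always keeps >= 0.2 mass


@dataclass(frozen=True)
class ChangePointMove:
    kind: str  # "birth" | "death" | "shift"
    position: int  # boundary inserted / deleted / its new location
    proposed: ChangePointVector
    q_forward: float
    q_reverse: float
    prior_log_ratio: float


def md_distance(x_left: np.ndarray, x_right: np.ndarray, lam: float) -> float:
    """Manhattan distance between two segments' (variance, mean) pairs.

    d = lam * (|var(l) - var(r)| + |mean(l) - mean(r)|), population variance.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    x_left = np.asarray(x_left, float)
    x_right = np.asarray(x_right, float)
    if len(x_left) < 2 or len(x_right) < 2:
        raise ValueError("segments must have length >= 2")
    return float(
        lam
        * (
            abs(np.var(x_left) - np.var(x_right))
            + abs(np.mean(x_left) - np.mean(x_right))
        )
    )


def _poisson_log_weight(j: int, lam_K: float) -> float:
    return j * log(lam_K) - lgamma(j + 1)


def prior_log_pmf(j: int, lam_K: float, K_max: int) -> float:
    """log P(#change points = j) under the truncated Poisson prior."""
    if not 0 <= j <= K_max - 1:
        return -np.inf
    ws = [_poisson_log_weight(i, lam_K) for i in range(K_max)]
    m = max(ws)
    norm = m + log(sum(np.exp(w - m) for w in ws))
    return _poisson_log_weight(j, lam_K) - norm


def n_configurations(j: int, T: int, min_seg_len: int) -> int:
    """Number of admissible boundary configurations with j change points.

    Compositions of the T-1 response times into j+1 contiguous segments of
    length >= min_seg_len.
    """
    n, K, m = T - 1, j + 1, min_seg_len
    if n - K * m < 0:
        return 0
    return comb(n - K * m + K - 1, K - 1)


def move_rates(j: int, lam_K: float, K_max: int) -> tuple[float, float, float]:
    """(birth, death, shift) kind probabilities at j change points."""
    b = _RATE_C * min(1.0, lam_K / (j + 1)) if j + 1 <= K_max - 1 else 0.0
    d = _RATE_C * min(1.0, j / lam_K) if j > 0 else 0.0
    return b, d, 1.0 - b - d


def _admissible_births(V: ChangePointVector, min_seg_len: int) -> list[int]:
    taus: list[int] = []
    for lo, hi in V.segments():
        # left part [lo, tau-1] and right part [tau, hi] both >= min_seg_len
        taus.extend(range(lo + min_seg_len, hi - min_seg_len + 2))
    return taus


def _birth_location_probs(
    V: ChangePointVector,
    x: np.ndarray,
    lam: float,
    min_seg_len: int,
) -> tuple[list[int], np.ndarray]:
    """Admissible birth positions and their exp(d)-weighted probabilities.

    ``x`` is the gene's expression indexed so that x[t-1] is the value at
    time t (i.e. the raw data row).  Sub-segment moments come from prefix
    sums, so the whole location scan is O(T).
    """
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cx2 = np.concatenate([[0.0], np.cumsum(x * x)])
    taus: list[int] = []
    ds: list[np.ndarray] = []
    for lo, hi in V.segments():
        ts = np.arange(lo + min_seg_len, hi - min_seg_len + 2)
        if len(ts) == 0:
            continue
        nl = ts - lo  # left covers times lo..tau-1
        nr = hi - ts + 1  # right covers times tau..hi
        sl, sl2 = cx[ts - 1] - cx[lo - 1], cx2[ts - 1] - cx2[lo - 1]
        sr, sr2 = cx[hi] - cx[ts - 1], cx2[hi] - cx2[ts - 1]
        ml, mr = sl / nl, sr / nr
        vl, vr = sl2 / nl - ml * ml, sr2 / nr - mr * mr
        ds.append(lam * (np.abs(vl - vr) + np.abs(ml - mr)))
        taus.extend(int(t) for t in ts)
    if not taus:
        return taus, np.empty(0)
    d = np.concatenate(ds)
    w = np.exp(d - d.max())
    return taus, w / w.sum()


def propose_birth(
    V: ChangePointVector,
    data: TimeSeriesDataset,
    g: int,
    *,
    lam: float,
    lam_K: float,
    K_max: int,
    min_seg_len: int,
    rng: np.random.Generator,
) -> ChangePointMove | None:
    """Insert a boundary at a Manhattan-distance-guided location.

    Returns None when no admissible location exists (counts as a rejection).
    """
    j = len(V.boundaries)
    if j + 1 > K_max - 1:
        raise ValueError("birth not admissible at K_max segments")
    taus, probs = _birth_location_probs(V, data.values[g], lam, min_seg_len)
    if not taus:
        return None
    i = int(rng.choice(len(taus), p=probs))
    tau = taus[i]
    proposed = ChangePointVector(V.T, tuple(sorted([*V.boundaries, tau])))
    b_j, _, _ = move_rates(j, lam_K, K_max)
    _, d_next, _ = move_rates(j + 1, lam_K, K_max)
    q_forward = b_j * float(probs[i])
    q_reverse = d_next / (j + 1)  # matched death deletes tau uniformly
    prior_lr = (
        prior_log_pmf(j + 1, lam_K, K_max)
        - prior_log_pmf(j, lam_K, K_max)
        + log(n_configurations(j, V.T, min_seg_len))
        - log(n_configurations(j + 1, V.T, min_seg_len))
    )
    return ChangePointMove("birth", tau, proposed, q_forward, q_reverse, prior_lr)


def propose_death(
    V: ChangePointVector,
    data: TimeSeriesDataset,
    g: int,
    *,
    lam: float,
    lam_K: float,
    K_max: int,
    min_seg_len: int,
    rng: np.random.Generator,
) -> ChangePointMove:
    """Delete a uniformly chosen boundary; reverse is the matched MD-birth."""
    j = len(V.boundaries)
    if j == 0:
        raise ValueError("death not admissible with a single segment")
    i = int(rng.integers(j))
    tau = V.boundaries[i]
    proposed = ChangePointVector(V.T, tuple(b for b in V.boundaries if b != tau))
    _, d_j, _ = move_rates(j, lam_K, K_max)
    b_prev, _, _ = move_rates(j - 1, lam_K, K_max)
    q_forward = d_j / j
    taus, probs = _birth_location_probs(proposed, data.values[g], lam, min_seg_len)
    q_reverse = b_prev * float(probs[taus.index(tau)])
    prior_lr = (
        prior_log_pmf(j - 1, lam_K, K_max)
        - prior_log_pmf(j, lam_K, K_max)
        + log(n_configurations(j, V.T, min_seg_len))
        - log(n_configurations(j - 1, V.T, min_seg_len))
    )
    return ChangePointMove("death", tau, proposed, q_forward, q_reverse, prior_lr)


def propose_shift(
    V: ChangePointVector,
    *,
    min_seg_len: int,
    rng: np.random.Generator,
) -> ChangePointMove | None:
    """Move a uniformly chosen boundary one step left or right (symmetric).

    Returns None (rejection) when the drawn shift would violate the minimum
    segment length or collide with a neighboring boundary.
    """
    j = len(V.boundaries)
    if j == 0:
        raise ValueError("shift not admissible with a single segment")
    i = int(rng.integers(j))
    step = -1 if rng.uniform() < 0.5 else 1
    tau_new = V.boundaries[i] + step
    new_bs = tuple(sorted(tau_new if k == i else b for k, b in enumerate(V.boundaries)))
    if len(set(new_bs)) != j:
        return None
    try:
        proposed = ChangePointVector(V.T, new_bs)
    except ValueError:
        return None
    if min(proposed.segment_lengths()) < min_seg_len:
        return None
    q = (1.0 / j) * 0.5
    return ChangePointMove("shift", tau_new, proposed, q, q, 0.0)


def accept_changepoint(
    move: ChangePointMove,
    log_ml_current: float,
    log_ml_proposed: float,
    rng: np.random.Generator,
) -> bool:
    """RJ-MCMC accept/reject.

    With all dimension-changing parameters integrated out of the marginal
    likelihood the acceptance probability is
    min(1, exp(dlogml + prior_log_ratio) * q_reverse / q_forward).
    """
    log_ratio = (
        log_ml_proposed
        - log_ml_current
        + move.prior_log_ratio
        + np.log(move.q_reverse)
        - np.log(move.q_forward)
    )
    if not np.isfinite(log_ratio):
        return False
    return bool(np.log(rng.uniform()) < min(0.0, log_ratio))
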