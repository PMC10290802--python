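"""Edge-score summaries and precision-recall evaluation.

An MCMC run yields, per iteration i and directed edge n -> j, an inclusion
indicator net(n,j)^i; the edge score is its mean over post-burn-in
iterations, i.e. the posterior inclusion probability.  Replicate runs are
compared through the elementwise mean of their score matrices and the summed
across-run variance (a convergence diagnostic: identical chains give 0).

Network reconstruction is scored against a gold-standard edge set with
recall R = TP/(TP+FN), precision P = TP/(TP+FP) at each threshold, the
harmonic-mean F-score, and the area under the PR curve using hyperbolic
(Davis-Goadrich) interpolation between achievable points: between counts
(TP_a, FP_a) and (TP_b, FP_b) the false positives grow linearly in TP, so
precision along the segment is x / (x + FP_a + s (x - TP_a)) with
s = (FP_b - FP_a)/(TP_b - TP_a), and the recall integral has a closed form.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log

import numpy as np

__all__ = [
    "EdgeScoreTrace",
    "edge_scores",
    "average_edge_scores",
    "edge_score_variance",
    "PRResult",
    "pr_metrics",
]


@dataclass
class EdgeScoreTrace:
    """Per-iteration directed-edge inclusion indicators.

    ``indicators`` has shape (I, G, G) with entry [i, n, j] = 1 iff edge
    n -> j is present at iteration i.
    """

    indicators: np.ndarray
    burn_in: int

    def __post_init__(self):
        ind = np.asarray(self.indicators)
        if ind.ndim != 3 or ind.shape[1] != ind.shape[2]:
            raise ValueError("indicators must have shape (I, G, G)")
        if not np.isin(ind, (0, 1)).all():
            raise ValueError("indicators must be 0/1")
        if not 0 <= self.burn_in < ind.shape[0]:
            raise ValueError("need 0 <= burn_in < number of iterations")
        self.indicators = ind

    @property
    def n_iterations(self) -> int:
        return self.indicators.shape[0]


def edge_scores(trace: EdgeScoreTrace) -> np.ndarray:
    """Posterior inclusion frequency of each edge over post-burn-in samples."""
    return trace.indicators[trace.burn_in :].mean(axis=0)


def average_edge_scores(per_run_scores: list[np.ndarray]) -> np.ndarray:
    """Elementwise mean of edge-score matrices across Q replicate runs."""
    if not per_run_scores:
        raise ValueError("need at least one run")
    mats = [np.asarray(m, float) for m in per_run_scores]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("score matrices have mismatched shapes")
    return np.mean(mats, axis=0)


def edge_score_variance(per_run_scores: list[np.ndarray]) -> float:
    """Sum over directed edges of the across-run population variance.

    The convergence summary for Q independent chains: 0 iff all runs agree
    exactly on every edge.
    """
    if len(per_run_scores) < 2:
        raise ValueError("need at least two runs for a variance")
    stacked = np.stack([np.asarray(m, float) for m in per_run_scores])
    return float(np.var(stacked, axis=0).sum())


@dataclass(frozen=True)
class PRResult:
    """PR points (recall, precision, threshold), AUC-PR and F-scores."""

    recall: np.ndarray
    precision: np.ndarray
    thresholds: np.ndarray
    auc_pr: float
    f_max: float
    f_at_half: float


def _dg_segment_area(tp_a, fp_a, tp_b, fp_b, n_pos) -> float:
    """Area under the interpolated precision over recall in [tp_a, tp_b]/P."""
    if tp_b == tp_a:
        return 0.0
    s = (fp_b - fp_a) / (tp_b - tp_a)
    # integral of x / ((1+s) x + a) dx / n_pos, a = fp_a - s * tp_a
    a = fp_a - s * tp_a
    b = 1.0 + s
    if a == 0.0:
        return (tp_b - tp_a) / b / n_pos
    upper = tp_b / b - (a / b**2) * log(b * tp_b + a)
    lower = tp_a / b - (a / b**2) * log(b * tp_a + a) if tp_a > 0 else -(
        a / b**2
    ) * log(a)
    return (upper - lower) / n_pos


def pr_metrics(
    scores: np.ndarray,
    gold: set[tuple[int, int]],
    *,
    self_loops: bool = False,
    thresholds: np.ndarray | None = None,
) -> PRResult:
    """Precision-recall evaluation of an edge-score matrix.

    ``gold`` is the set of true directed edges as (source, target) index
    pairs; candidate edges are all ordered pairs (off-diagonal unless
    ``self_loops``).  E(xi) contains the edges with score strictly above xi;
    by default the threshold grid is the sorted unique scores (the exact
    achievable PR points).  The reported F-score is the maximum over the
    grid; ``f_at_half`` evaluates F at xi = 0.5 for reference.
    """
    scores = np.asarray(scores, float)
    if not gold:
        raise ValueError("empty gold standard: prevalence undefined")
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must lie in [0, 1]")
    G = scores.shape[0]
    pairs = [
        (i, j) for i in range(G) for j in range(G) if self_loops or i != j
    ]
    y = np.asarray([(i, j) in gold for i, j in pairs], dtype=bool)
    s = np.asarray([scores[i, j] for i, j in pairs])
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("gold standard contains no candidate edges")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # group ties: cumulative TP/FP after each distinct score level
    distinct = np.nonzero(np.diff(s_sorted))[0]
    ends = np.append(distinct, len(s_sorted) - 1)
    tp = np.cumsum(y_sorted)[ends].astype(float)
    fp = np.cumsum(~y_sorted)[ends].astype(float)
    levels = s_sorted[ends]

    keep = (tp + fp) > 0
    tp, fp, levels = tp[keep], fp[keep], levels[keep]
    recall = tp / n_pos
    with np.errstate(invalid="ignore"):
        precision = tp / (tp + fp)

    area = 0.0
    prev_tp, prev_fp = 0.0, 0.0
    for t, f in zip(tp, fp):
        area += _dg_segment_area(prev_tp, prev_fp, t, f, n_pos)
        prev_tp, prev_fp = t, f

    def _f(r, p):
        return 0.0 if r + p == 0 else 2 * r * p / (r + p)

    f_scores = [_f(r, p) for r, p in zip(recall, precision)]
    f_max = max(f_scores) if f_scores else 0.0

    sel = s > 0.5
    tp_h = float(np.sum(y & sel))
    fp_h = float(np.sum(~y & sel))
    r_h = tp_h / n_pos
    p_h = tp_h / (tp_h + fp_h) if tp_h + fp_h > 0 else 0.0
    f_half = _f(r_h, p_h)

    return PRResult(
        recall=recall,
        precision=precision,
        thresholds=levels,
        auc_pr=float(area),
        f_max=float(f_max),
        f_at_half=float(f_half),
    )
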