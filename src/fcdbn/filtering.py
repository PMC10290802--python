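"""Segmented node-correlation filter biasing parent proposals.

Short non-stationary series make a single whole-series Pearson correlation
misleading, so correlations are accumulated segment-wise: at each sweep one
segment of the target gene is drawn with probability proportional to its
length, correlated with the other gene over the same time span, and folded
into a running estimate R via a convex-combination recursion weighted by
|segment| / T.  The running weight C makes long segments count more and makes
late updates progressively weaker (the update at step n with constant weight
w moves R by w / (C0 + n w)).

R then biases parent-addition proposals: candidate g' gets weight
(|R[g, g']| + eps) ** temperature.  Temperature 0 makes the filter inert
(uniform proposals, the plain-DBN baseline); the absolute value treats strong
repression as informative as activation.
"""

from __future__ import annotations

import numpy as np

from .data import ChangePointVector, TimeSeriesDataset

__all__ = ["FilterMatrix", "segment_pearson", "update_filter", "proposal_weights"]


def segment_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation with population normalization.

    Returns 0.0 when either vector is constant (undefined correlation is
    treated as "no evidence").
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need vectors of length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(xc @ xc))
    sy = float(np.sqrt(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = float((xc @ yc) / (sx * sy))
    return max(-1.0, min(1.0, r))


class FilterMatrix:
    """Running correlation estimate R with per-pair auxiliary weight C.

    ``R[g, g']`` estimates the association between target gene g and
    candidate parent g'; entries stay in [-1, 1] because every update is a
    convex combination.  C is kept per ordered pair so a pair whose update is
    skipped (undefined correlation) is not corrupted.
    """

    def __init__(self, G: int):
        if G < 2:
            raise ValueError("need at least 2 genes")
        self.R = np.zeros((G, G))
        self.C = np.ones((G, G))

    @property
    def n_genes(self) -> int:
        return self.R.shape[0]

    def copy(self) -> "FilterMatrix":
        out = FilterMatrix(self.n_genes)
        out.R = self.R.copy()
        out.C = self.C.copy()
        return out

    def to_frame(self, gene_names):
        import pandas as pd

        return pd.DataFrame(self.R, index=gene_names, columns=gene_names)


def _overlap_pearson(
    data: TimeSeriesDataset,
    g: int,
    gp: int,
    span: tuple[int, int],
    V_other: ChangePointVector,
) -> float | None:
    """Correlation of g and g' over a response-time span, segment-aware.

    When the span straddles several segments of g', each overlap of length
    >= 2 contributes its own correlation, weighted by overlap length.
    Returns None when no overlap supports a correlation.
    """
    lo, hi = span
    total = 0.0
    acc = 0.0
    for olo, ohi in V_other.segments():
        a, b = max(lo, olo), min(hi, ohi)
        if b - a + 1 < 2:
            continue
        idx = np.arange(a - 1, b)  # column of time t is t-1
        r = segment_pearson(data.values[g, idx], data.values[gp, idx])
        acc += r * (b - a + 1)
        total += b - a + 1
    if total == 0.0:
        return None
    return acc / total


def update_filter(
    F: FilterMatrix,
    data: TimeSeriesDataset,
    V_all: list[ChangePointVector],
    rng: np.random.Generator,
) -> FilterMatrix:
    """One filter sweep: update R[g, g'] for every ordered gene pair in place.

    For each target g a segment k is drawn with probability proportional to
    its length; the recursion
    ``R <- (R * C + P * w) / (C + w)``, ``C <- C + w`` with w = |X_{g,k}| / T
    then folds in the segment correlation P with each other gene.
    """
    G, T = data.n_genes, data.n_times
    for g in range(G):
        lengths = np.asarray(V_all[g].segment_lengths(), float)
        k = int(rng.choice(len(lengths), p=lengths / lengths.sum()))
        span = V_all[g].segments()[k]
        w = lengths[k] / T
        for gp in range(G):
            if gp == g:
                continue
            P = _overlap_pearson(data, g, gp, span, V_all[gp])
            if P is None:
                continue  # undefined correlation: skip pair, C unchanged
            C = F.C[g, gp]
            F.R[g, gp] = (F.R[g, gp] * C + P * w) / (C + w)
            F.C[g, gp] = C + w
    return F


def proposal_weights(
    F: FilterMatrix,
    g: int,
    candidates,
    temperature: float = 1.0,
    epsilon: float = 0.01,
) -> np.ndarray:
    """Normalized add-proposal probabilities over candidate parents of g.

    Weight of candidate g' is (|R[g, g']| + eps) ** temperature; eps > 0
    keeps every candidate reachable (ergodicity), temperature 0 gives the
    uniform baseline.
    """
    cand = list(candidates)
    if not cand:
        raise ValueError("empty candidate set")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    w = (np.abs(F.R[g, cand]) + epsilon) ** temperature
    return w / w.sum()
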