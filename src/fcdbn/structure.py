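"""Metropolis-Hastings sampling of per-gene parent sets.

Moves add or remove one parent.  A proposal draws a neighbor from S(pi) — the
one-edit neighborhood respecting the fan-in bound — with removal neighbors
carrying unit weight and addition neighbors carrying ``n_add * w_p`` where
w_p are the normalized filter weights over candidate parents.  At temperature
0 every neighbor has weight 1, i.e. the proposal is uniform over S(pi) and
the Hastings factor reduces to the classical |S(pi)| / |S(pi')| correction;
at temperature > 0 the filter reshapes only the *proposal*, never the target,
because the exact forward/reverse probabilities enter the acceptance ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .filtering import FilterMatrix, proposal_weights

__all__ = [
    "StructureMove",
    "neighborhood",
    "neighborhood_size",
    "propose_structure",
    "accept_structure",
]


@dataclass(frozen=True)
class StructureMove:
    kind: str  # "add" | "remove"
    gene: int
    parent: int
    proposed: frozenset
    q_forward: float
    q_reverse: float


def _add_candidates(pi: frozenset, g: int, G: int, self_loops: bool) -> list[int]:
    return [p for p in range(G) if p not in pi and (self_loops or p != g)]


def neighborhood(
    pi: frozenset, g: int, G: int, fan_in: int, self_loops: bool = False
) -> set[frozenset]:
    """All parent sets one admissible add or remove away from pi."""
    out: set[frozenset] = set()
    if len(pi) < fan_in:
        for p in _add_candidates(pi, g, G, self_loops):
            out.add(pi | {p})
    for p in pi:
        out.add(pi - {p})
    return out


def neighborhood_size(
    pi: frozenset, g: int, G: int, fan_in: int, self_loops: bool = False
) -> int:
    n_add = len(_add_candidates(pi, g, G, self_loops)) if len(pi) < fan_in else 0
    return n_add + len(pi)


def propose_structure(
    pi: frozenset,
    F: FilterMatrix,
    g: int,
    *,
    fan_in: int,
    self_loops: bool = False,
    temperature: float = 1.0,
    epsilon: float = 0.01,
    rng: np.random.Generator,
) -> StructureMove:
    """Draw one add/remove move with exact forward and reverse probabilities."""
    G = F.n_genes
    adds = _add_candidates(pi, g, G, self_loops) if len(pi) < fan_in else []
    rems = sorted(pi)
    n_add, n_rem = len(adds), len(rems)
    total = n_add + n_rem
    if total == 0:
        raise ValueError("no admissible structure move")

    if n_add:
        w_add = proposal_weights(F, g, adds, temperature, epsilon)  # sums to 1
        # neighbor weights: removals 1 each, addition of p gets n_add * w_p,
        # so the total neighborhood weight is always |S(pi)|
        probs = np.concatenate([np.full(n_rem, 1.0), n_add * w_add]) / total
    else:
        probs = np.full(n_rem, 1.0) / total

    j = int(rng.choice(total, p=probs))
    if j < n_rem:
        kind, parent = "remove", rems[j]
        proposed = pi - {parent}
        q_forward = probs[j]
        # reverse: add `parent` back from `proposed`
        adds_r = _add_candidates(proposed, g, G, self_loops)
        total_r = len(adds_r) + len(proposed)
        w_r = proposal_weights(F, g, adds_r, temperature, epsilon)
        q_reverse = len(adds_r) * float(w_r[adds_r.index(parent)]) / total_r
    else:
        kind, parent = "add", adds[j - n_rem]
        proposed = pi | {parent}
        q_forward = probs[j]
        # reverse: remove `parent` from `proposed` (unit weight)
        adds_r = (
            _add_candidates(proposed, g, G, self_loops)
            if len(proposed) < fan_in
            else []
        )
        total_r = len(adds_r) + len(proposed)
        q_reverse = 1.0 / total_r
    return StructureMove(kind, g, parent, frozenset(proposed), float(q_forward), q_reverse)


def accept_structure(
    move: StructureMove,
    log_ml_current: float,
    log_ml_proposed: float,
    rng: np.random.Generator,
    prior_log_ratio: float = 0.0,
) -> bool:
    """M-H accept/reject with the Hastings correction for the biased proposal.

    Acceptance probability
    min(1, exp(log_ml' - log_ml + prior_log_ratio) * q_reverse / q_forward).
    """
    log_ratio = (
        log_ml_proposed
        - log_ml_current
        + prior_log_ratio
        + np.log(move.q_reverse)
        - np.log(move.q_forward)
    )
    if not np.isfinite(log_ratio):
        if log_ratio > 0:  # +inf: proposed infinitely better — cannot happen for
            return True  # finite marginals, but accept rather than stall
        if np.isnan(log_ratio):
            warnings.warn("non-finite structure acceptance ratio; rejecting")
            return False
        return False  # -inf
    return bool(np.log(rng.uniform()) < min(0.0, log_ratio))
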