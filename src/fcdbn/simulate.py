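"""Piecewise linear-Gaussian network simulator.

Generates short non-stationary expression series from a known lag-1 network:
x_g(t) = intercept_{g,k} + sum_{p in pi_g} w_{g,k,p} x_p(t-1) + N(0, sd^2),
with k the segment of gene g covering time t.  Each preset fixes the ground
truth (topology, per-segment coefficients, change points) so samplers can be
scored against it.

The bundled topologies are synthetic stand-ins shaped like the classic
benchmarks in this literature: a 5-gene, 35-point cyclic network with one
change point per gene, and an 11-node signalling cascade (PIP3, PLCG, PIP2,
PKC, PKA, JNK, P38, RAF, MEK, ERK, AKT) with the 20 directed interactions of
the consensus RAF pathway and two regimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ChangePointVector, TimeSeriesDataset, write_expression_matrix

__all__ = ["SimulationConfig", "SimulationTruth", "simulate", "make_benchmark_suite"]

_OVERFLOW_GUARD = 1e6
_BURN_IN_STEPS = 10  # discarded warm-up steps so segment-1 stats settle


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth description of one simulated dataset.

    ``edges`` maps (parent, child) to a tuple of per-segment coefficients
    (one per segment of the *child*); ``changepoints`` maps gene -> boundary
    positions in response-time coordinates; ``intercepts`` maps gene -> per-
    segment intercepts (default zeros).
    """

    G: int
    T: int
    edges: dict[tuple[int, int], tuple[float, ...]]
    changepoints: dict[int, tuple[int, ...]] = field(default_factory=dict)
    intercepts: dict[int, tuple[float, ...]] = field(default_factory=dict)
    noise_sd: float = 0.1
    seed: int = 0
    gene_names: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.G < 2 or self.T < 3:
            raise ValueError("need G >= 2 and T >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for (p, c), ws in self.edges.items():
            if not (0 <= p < self.G and 0 <= c < self.G):
                raise ValueError(f"edge ({p}, {c}) out of range")
            if not all(np.isfinite(ws)):
                raise ValueError(f"edge ({p}, {c}) has non-finite coefficients")
            if len(ws) != self.n_segments(c):
                raise ValueError(
                    f"edge ({p}, {c}): {len(ws)} coefficients for "
                    f"{self.n_segments(c)} segments"
                )

    def n_segments(self, g: int) -> int:
        return len(self.changepoints.get(g, ())) + 1

    def changepoint_vector(self, g: int) -> ChangePointVector:
        return ChangePointVector(self.T, self.changepoints.get(g, ()))


@dataclass(frozen=True)
class SimulationTruth:
    """What the simulator knows: edges, coefficients, change points."""

    edges: frozenset[tuple[int, int]]
    coefficients: dict[tuple[int, int], tuple[float, ...]]
    changepoints: dict[int, tuple[int, ...]]

    def parent_sets(self, G: int) -> list[frozenset]:
        return [frozenset(p for p, c in self.edges if c == g) for g in range(G)]


def simulate(config: SimulationConfig) -> tuple[TimeSeriesDataset, SimulationTruth]:
    """Generate one dataset; identical seeds give identical output."""
    G, T = config.G, config.T
    rng = np.random.default_rng(config.seed)
    parents: dict[int, list[int]] = {g: [] for g in range(G)}
    for p, c in config.edges:
        parents[c].append(p)

    def step(x_prev: np.ndarray, seg_idx: list[int], noisy: bool) -> np.ndarray:
        x = np.empty(G)
        for g in range(G):
            k = seg_idx[g]
            b = config.intercepts.get(g, None)
            val = b[k] if b is not None else 0.0
            for p in parents[g]:
                val += config.edges[(p, g)][k] * x_prev[p]
            if noisy and config.noise_sd > 0:
                val += config.noise_sd * rng.standard_normal()
            x[g] = val
        if np.any(np.abs(x) > _OVERFLOW_GUARD):
            raise ValueError(
                "explosive dynamics (|x| exceeded overflow guard); "
                "use smaller coefficients"
            )
        return x

    Vs = [config.changepoint_vector(g) for g in range(G)]
    x = rng.standard_normal(G)
    for _ in range(_BURN_IN_STEPS):  # warm up under segment-1 dynamics
        x = step(x, [0] * G, noisy=True)

    values = np.empty((G, T))
    values[:, 0] = x
    for t in range(2, T + 1):
        seg_idx = [Vs[g].segment_of(t) for g in range(G)]
        values[:, t - 1] = step(values[:, t - 2], seg_idx, noisy=True)

    names = config.gene_names or tuple(f"G{i + 1}" for i in range(G))
    truth = SimulationTruth(
        frozenset(config.edges),
        dict(config.edges),
        {g: tuple(config.changepoints.get(g, ())) for g in range(G)},
    )
    return TimeSeriesDataset(values, names), truth


# --- presets ---------------------------------------------------------------

_RAF_NODES = (
    "PIP3", "PLCG", "PIP2", "PKC", "PKA", "JNK", "P38", "RAF", "MEK", "ERK", "AKT",
)
# consensus RAF signalling topology: 20 directed interactions, max in-degree 3
_RAF_EDGES = (
    ("PIP3", "PLCG"), ("PIP3", "PIP2"), ("PIP3", "AKT"),
    ("PLCG", "PIP2"), ("PLCG", "PKC"),
    ("PIP2", "PKC"),
    ("PKC", "PKA"), ("PKC", "RAF"), ("PKC", "MEK"), ("PKC", "JNK"), ("PKC", "P38"),
    ("PKA", "RAF"), ("PKA", "MEK"), ("PKA", "ERK"), ("PKA", "AKT"),
    ("PKA", "JNK"), ("PKA", "P38"),
    ("RAF", "MEK"), ("MEK", "ERK"), ("ERK", "AKT"),
)

# 5-gene cyclic toy: in-degrees <= 2, every gene regulated
_YEAST_LIKE_EDGES = ((0, 1), (1, 2), (2, 0), (2, 3), (3, 4), (4, 0))


def _alternating(w: float, K: int) -> tuple[float, ...]:
    """Per-segment coefficients with sign flips, so regimes differ in both
    mean and variance structure."""
    return tuple(w * (-1) ** k for k in range(K))


def make_benchmark_suite(preset: str) -> list[SimulationConfig]:
    """Named simulation presets.

    ``yeast_like``: 5 genes x 35 time points, one change point per gene.
    ``raf_like``: 11 nodes, the 20-edge RAF cascade, two regimes, T = 50.
    ``null``: 5 genes, no edges (no positives — evaluation must refuse).
    """
    if preset == "yeast_like":
        G, T, w = 5, 35, 0.9
        cps = {g: (18,) for g in range(G)}
        edges = {e: _alternating(w, 2) for e in _YEAST_LIKE_EDGES}
        return [
            SimulationConfig(
                G=G, T=T, edges=edges, changepoints=cps, noise_sd=0.1, seed=0
            )
        ]
    if preset == "raf_like":
        G, T, w = 11, 50, 0.7
        idx = {n: i for i, n in enumerate(_RAF_NODES)}
        cps = {g: (26,) for g in range(G)}
        edges = {(idx[p], idx[c]): _alternating(w, 2) for p, c in _RAF_EDGES}
        return [
            SimulationConfig(
                G=G, T=T, edges=edges, changepoints=cps, noise_sd=0.1, seed=0,
                gene_names=_RAF_NODES,
            )
        ]
    if preset == "null":
        return [SimulationConfig(G=5, T=35, edges={}, noise_sd=0.1, seed=0)]
    raise ValueError(
        f"unknown preset {preset!r}; available: yeast_like, raf_like, null"
    )


def write_truth(
    config: SimulationConfig,
    truth: SimulationTruth,
    data: TimeSeriesDataset,
    prefix,
) -> None:
    """Write the expression matrix, truth edge list, and truth change points."""
    write_expression_matrix(data, f"{prefix}_expression.tsv")
    with open(f"{prefix}_edges.tsv", "wt") as fh:
        fh.write("source\ttarget\n")
        for p, c in sorted(truth.edges):
            fh.write(f"{data.gene_names[p]}\t{data.gene_names[c]}\n")
    with open(f"{prefix}_changepoints.tsv", "wt") as fh:
        fh.write("gene\tboundaries\n")
        for g in range(config.G):
            bs = ",".join(str(b) for b in truth.changepoints.get(g, ()))
            fh.write(f"{data.gene_names[g]}\t{bs}\n")
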