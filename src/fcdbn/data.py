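"""Core containers and I/O for gene-expression time series.

A dataset is a G x T matrix of expression values (genes in rows, equally
spaced time points in columns).  All regressions in this package are lag-1:
gene g at time t is regressed on its parents' values at time t-1, so the
*response times* are t = 2..T and every per-gene segmentation
(:class:`ChangePointVector`) is expressed in those response-time coordinates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesDataset",
    "ChangePointVector",
    "ParentSet",
    "NetworkStructure",
    "GeneParams",
    "Level2Hyper",
    "load_expression_matrix",
    "build_design",
    "write_edge_scores",
    "read_edge_scores",
    "load_edge_list",
]


@dataclass(frozen=True)
class TimeSeriesDataset:
    """Expression matrix with gene labels.

    Parameters
    ----------
    values : ndarray, shape (G, T)
        Expression levels, genes in rows.  Never modified by the loader.
    gene_names : tuple of str
        Unique row labels.
    """

    values: np.ndarray
    gene_names: tuple[str, ...]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_names", tuple(self.gene_names))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D (genes x times) array")
        G, T = values.shape
        if G < 2:
            raise ValueError(f"need at least 2 genes, got {G}")
        if T < 3:
            raise ValueError(f"need at least 3 time points, got {T}")
        if len(self.gene_names) != G:
            raise ValueError("gene_names length does not match row count")
        if len(set(self.gene_names)) != G:
            raise ValueError("gene_names must be unique")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression matrix contains missing/non-finite values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    def standardized(self) -> "TimeSeriesDataset":
        """Return a copy with each gene z-scored (population sd).

        Constant genes are centred but left unscaled.
        """
        v = self.values
        mu = v.mean(axis=1, keepdims=True)
        sd = v.std(axis=1, keepdims=True)
        sd = np.where(sd > 0, sd, 1.0)
        return TimeSeriesDataset((v - mu) / sd, self.gene_names)

    def index_of(self, name: str) -> int:
        return self.gene_names.index(name)


@dataclass(frozen=True)
class ChangePointVector:
    """Per-gene allocation of response times 2..T to contiguous segments.

    ``boundaries`` holds change-point positions tau in response-time
    coordinates: a boundary at tau means one segment ends at tau-1 and the
    next starts at tau.  With j boundaries there are K = j + 1 segments
    partitioning {2..T}.
    """

    T: int
    boundaries: tuple[int, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "boundaries", tuple(int(b) for b in self.boundaries))
        if self.T < 3:
            raise ValueError("T must be >= 3")
        bs = self.boundaries
        if any(b2 <= b1 for b1, b2 in zip(bs, bs[1:])):
            raise ValueError("boundaries must be strictly increasing")
        if bs and (bs[0] < 3 or bs[-1] > self.T):
            raise ValueError("boundaries must lie within 3..T")

    @property
    def n_segments(self) -> int:
        return len(self.boundaries) + 1

    def segments(self) -> list[tuple[int, int]]:
        """Inclusive (start, stop) response-time ranges of the segments."""
        edges = [2, *self.boundaries, self.T + 1]
        return [(edges[i], edges[i + 1] - 1) for i in range(len(edges) - 1)]

    def segment_lengths(self) -> list[int]:
        return [hi - lo + 1 for lo, hi in self.segments()]

    def segment_of(self, t: int) -> int:
        """Index of the segment covering response time t."""
        if not 2 <= t <= self.T:
            raise ValueError(f"response time {t} outside 2..{self.T}")
        return int(np.searchsorted(self.boundaries, t, side="right"))

    def validate(self, min_seg_len: int, K_max: int) -> None:
        if self.n_segments > K_max:
            raise ValueError(f"{self.n_segments} segments exceeds K_max={K_max}")
        if min(self.segment_lengths()) < min_seg_len:
            raise ValueError(f"segment shorter than min_seg_len={min_seg_len}")


# Parent sets are plain frozensets of gene indices; NetworkStructure collects
# one per gene.  ParentSet is an alias kept for interface clarity.
ParentSet = frozenset


@dataclass(frozen=True)
class NetworkStructure:
    """One parent set per gene: the sampled network M = (pi_1, ..., pi_G)."""

    parent_sets: tuple[frozenset, ...]

    def __post_init__(self):
        object.__setattr__(
            self, "parent_sets", tuple(frozenset(p) for p in self.parent_sets)
        )

    def validate(self, G: int, fan_in: int, self_loops: bool) -> None:
        if len(self.parent_sets) != G:
            raise ValueError("need one parent set per gene")
        for g, pi in enumerate(self.parent_sets):
            if len(pi) > fan_in:
                raise ValueError(f"gene {g}: |parents|={len(pi)} exceeds fan_in={fan_in}")
            if not self_loops and g in pi:
                raise ValueError(f"gene {g}: self-loop not allowed")
            if any(not 0 <= p < G for p in pi):
                raise ValueError(f"gene {g}: parent index out of range")

    def edges(self) -> set[tuple[int, int]]:
        return {(p, g) for g, pi in enumerate(self.parent_sets) for p in pi}


@dataclass
class GeneParams:
    """Per-gene sampled parameters: segment coefficients and hyperparameters.

    ``w`` has one coefficient vector per segment (length |parents|+1, the
    intercept first); ``delta_inv`` is the inverse signal-to-noise ratio,
    ``sigma2_inv`` the inverse noise variance.
    """

    w: list[np.ndarray]
    delta_inv: float
    sigma2_inv: float

    def __post_init__(self):
        if self.delta_inv <= 0 or self.sigma2_inv <= 0:
            raise ValueError("delta_inv and sigma2_inv must be positive")


@dataclass(frozen=True)
class Level2Hyper:
    """Fixed top-level Gamma hyperparameters of the hierarchical model.

    (A_delta, B_delta) govern the inverse signal-to-noise ratio delta^-1,
    (A_sigma, B_sigma) the inverse noise variance sigma^-2.  Defaults are the
    conventional weakly-informative settings for this model family.
    """

    A_delta: float = 2.0
    B_delta: float = 0.2
    A_sigma: float = 0.005
    B_sigma: float = 0.005

    def __post_init__(self):
        if min(self.A_delta, self.B_delta, self.A_sigma, self.B_sigma) <= 0:
            raise ValueError("all level-2 hyperparameters must be positive")


def load_expression_matrix(path, delimiter: str = "\t") -> TimeSeriesDataset:
    """Read a genes x times expression matrix from a delimited text file.

    The first column carries gene names; a header row is auto-detected (a
    first row whose non-label cells are not all numeric is treated as a
    header).  Values are returned exactly as stored — no normalization.
    """
    with open(path, "rt") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise ValueError(f"{path}: empty file")

    rows = [ln.split(delimiter) for ln in lines]

    def _numeric(cells: list[str]) -> bool:
        try:
            [float(c) for c in cells]
            return True
        except ValueError:
            return False

    start = 0
    if not _numeric(rows[0][1:]):
        start = 1  # header row
    body = rows[start:]
    if not body:
        raise ValueError(f"{path}: no data rows")

    width = len(body[0])
    names: list[str] = []
    values = []
    for i, cells in enumerate(body):
        if len(cells) != width:
            raise ValueError(
                f"{path}: ragged row {start + i + 1} "
                f"({len(cells)} fields, expected {width})"
            )
        names.append(cells[0])
        row = []
        for j, c in enumerate(cells[1:], start=2):
            try:
                row.append(float(c))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell at row {start + i + 1}, column {j}: {c!r}"
                ) from None
        values.append(row)
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"{path}: duplicate gene name(s): {', '.join(dup)}")
    return TimeSeriesDataset(np.asarray(values, dtype=float), tuple(names))


def write_expression_matrix(data: TimeSeriesDataset, path, delimiter: str = "\t") -> None:
    """Write a dataset in the format :func:`load_expression_matrix` reads."""
    header = delimiter.join(["gene", *(f"t{t}" for t in range(1, data.n_times + 1))])
    with open(path, "wt") as fh:
        fh.write(header + "\n")
        for name, row in zip(data.gene_names, data.values):
            fh.write(delimiter.join([name, *(repr(float(v)) for v in row)]) + "\n")


def build_design(
    data: TimeSeriesDataset,
    g: int,
    parents: Iterable[int],
    segment: Iterable[int],
) -> tuple[np.ndarray, np.ndarray]:
    """Lag-1 design for gene g on a set of response times.

    Returns ``(y, X)`` where ``y[t]`` is gene g's expression at response time
    t and the matching row of ``X`` is ``[1, x_p1(t-1), x_p2(t-1), ...]`` for
    the sorted parents.  Response times must lie in 2..T (time 1 has no
    lagged predictor).
    """
    times = sorted(int(t) for t in segment)
    if times and times[0] < 2:
        raise ValueError("response time 1 has no lagged predictor")
    if times and times[-1] > data.n_times:
        raise ValueError("response time beyond T")
    ps = sorted(parents)
    idx = np.asarray(times, dtype=int) - 1  # 0-based column of time t
    y = data.values[g, idx]
    X = np.empty((len(times), len(ps) + 1))
    X[:, 0] = 1.0
    for j, p in enumerate(ps, start=1):
        X[:, j] = data.values[p, idx - 1]
    return y, X


def write_edge_scores(
    scores: np.ndarray,
    gene_names: Sequence[str],
    path,
    *,
    self_loops: bool = False,
) -> None:
    """Write a G x G score matrix as a three-column TSV (source, target, score).

    Rows are sorted by descending score; scores must lie in [0, 1].
    Self-edges are emitted only when ``self_loops`` is set.
    """
    scores = np.asarray(scores, dtype=float)
    G = len(gene_names)
    if scores.shape != (G, G):
        raise ValueError("score matrix shape does not match gene_names")
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("edge scores must lie in [0, 1]")
    rows = [
        (gene_names[i], gene_names[j], scores[i, j])
        for i in range(G)
        for j in range(G)
        if self_loops or i != j
    ]
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    tmp = f"{path}.tmp{os.getpid()}"
    with open(tmp, "wt") as fh:
        fh.write("source\ttarget\tscore\n")
        for s, t, v in rows:
            fh.write(f"{s}\t{t}\t{float(v)!r}\n")
    os.replace(tmp, path)


def read_edge_scores(path, gene_names: Sequence[str]) -> np.ndarray:
    """Read a three-column edge-score TSV back into a G x G matrix."""
    index = {n: i for i, n in enumerate(gene_names)}
    scores = np.zeros((len(gene_names), len(gene_names)))
    df = pd.read_csv(path, sep="\t")
    for src, tgt, val in df.itertuples(index=False):
        scores[index[str(src)], index[str(tgt)]] = float(val)
    return scores


def load_edge_list(path, gene_names: Sequence[str]) -> set[tuple[int, int]]:
    """Read a two-column (source, target) TSV gold standard as index pairs.

    A header row is auto-detected (both cells appearing in ``gene_names``
    means data; otherwise the first row is skipped if either cell is unknown
    and the rest parse).
    """
    index = {n: i for i, n in enumerate(gene_names)}
    edges: set[tuple[int, int]] = set()
    with open(path, "rt") as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    for k, ln in enumerate(lines):
        cells = ln.split("\t")
        if len(cells) < 2:
            raise ValueError(f"{path}: line {k + 1} has fewer than two columns")
        s, t = cells[0], cells[1]
        if s not in index or t not in index:
            if k == 0:
                continue  # header
            raise ValueError(f"{path}: unknown gene in edge {s} -> {t}")
        edges.add((index[s], index[t]))
    return edges
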