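"""Model and results objects for filter-coupled nonhomogeneous DBN inference.

:class:`FCDBN` wraps a gene-expression time-series dataset together with the
sampler configuration; :meth:`FCDBN.fit` runs the MCMC and returns a
:class:`FCDBNResults` carrying posterior edge scores, acceptance diagnostics
and change-point summaries.  One sweep of the chain updates, in order,

1. per-gene parameters by Gibbs sampling (sigma^-2 from its collapsed
   conditional, segment coefficients w, then the inverse signal-to-noise
   ratio delta^-1),
2. each gene's change-point vector by one reversible-jump move
   (Manhattan-distance-guided birth / death / boundary shift),
3. the node-correlation filter matrix (skipped at temperature 0, where the
   proposal is the uniform baseline),
4. each gene's parent set by one Metropolis-Hastings move with the
   filter-biased proposal and exact Hastings correction.

Edge n -> j is recorded present at a sweep iff n is in gene j's parent set;
the posterior inclusion frequency over post-burn-in sweeps is the edge score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.special import gammaln

from . import changepoints as cp
from .data import ChangePointVector, Level2Hyper, TimeSeriesDataset
from .evaluation import (
    EdgeScoreTrace,
    average_edge_scores,
    edge_score_variance,
    edge_scores,
    pr_metrics,
)
from .filtering import FilterMatrix, update_filter
from .regression import (
    CrossProductCache,
    sample_delta_inv,
    sample_sigma2_inv,
    segment_quadratic_terms,
)
from .structure import accept_structure, neighborhood_size, propose_structure

__all__ = ["RunConfig", "FCDBN", "FCDBNResults", "ReplicateResults"]


@dataclass(frozen=True)
class RunConfig:
    """Run-level knobs of the sampler.

    ``lam`` scales the Manhattan-distance birth weights (0 = distance-blind
    births); ``temperature``/``epsilon`` shape the filter-biased parent
    proposal (temperature 0 = uniform baseline, the filter is fully inert);
    ``lambda_K`` is the truncated-Poisson prior mean of the number of change
    points per gene.
    """

    iterations: int = 20_000
    burn_in: int | None = None  # default: iterations // 2
    seed: int | None = None
    fan_in: int = 3
    K_max: int = 10
    min_seg_len: int | None = None  # default: max(2, fan_in + 2)
    lam: float = 1.0
    temperature: float = 1.0
    epsilon: float = 0.01
    lambda_K: float = 1.0
    hyper: Level2Hyper = field(default_factory=Level2Hyper)
    standardize: bool = True
    self_loops: bool = False

    def resolved(self) -> "RunConfig":
        out = self
        if out.burn_in is None:
            out = replace(out, burn_in=out.iterations // 2)
        if out.min_seg_len is None:
            out = replace(out, min_seg_len=max(2, out.fan_in + 2))
        return out

    def validate(self, T: int) -> None:
        c = self.resolved()
        if c.iterations <= 0 or not 0 <= c.burn_in < c.iterations:
            raise ValueError("need iterations > burn_in >= 0")
        if c.fan_in < 0 or c.K_max < 1 or c.min_seg_len < 2:
            raise ValueError("fan_in >= 0, K_max >= 1, min_seg_len >= 2 required")
        if c.lam < 0 or c.temperature < 0 or c.epsilon <= 0 or c.lambda_K <= 0:
            raise ValueError("lam, temperature >= 0; epsilon, lambda_K > 0")
        if T - 1 < c.min_seg_len:
            raise ValueError("series too short for one segment of min_seg_len")


class FCDBN:
    """Filter-coupled nonhomogeneous dynamic Bayesian network model.

    Parameters
    ----------
    data : TimeSeriesDataset or DataFrame
        G x T expression matrix (genes in rows).  Standardized per gene at
        construction unless ``standardize=False``.
    **config
        Any :class:`RunConfig` field (fan_in, K_max, temperature, ...).

    Examples
    --------
    >>> from fcdbn import FCDBN, make_benchmark_suite, simulate
    >>> data, truth = simulate(make_benchmark_suite("yeast_like")[0])
    >>> res = FCDBN(data).fit(iterations=2000, seed=1)
    >>> res.edge_score_matrix.shape
    (5, 5)
    """

    def __init__(self, data, **config):
        if isinstance(data, pd.DataFrame):
            data = TimeSeriesDataset(data.to_numpy(float), tuple(map(str, data.index)))
        if not isinstance(data, TimeSeriesDataset):
            raise TypeError("data must be a TimeSeriesDataset or DataFrame")
        self.config = RunConfig(**config)
        self.config.validate(data.n_times)
        self.raw_data = data
        self.data = data.standardized() if self.config.standardize else data
        self._cache = CrossProductCache(self.data)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **config) -> "FCDBN":
        return cls(df, **config)

    # -- sampling ----------------------------------------------------------

    def fit(self, *, iterations=None, burn_in=None, seed=None, rng=None,
            **overrides) -> "FCDBNResults":
        """Run the MCMC and return results.

        ``seed`` (or an explicit ``rng``) fixes all randomness; fit-time
        keyword arguments override the construction-time configuration.
        """
        cfg = self.config
        if iterations is not None:
            cfg = replace(cfg, iterations=int(iterations))
        if burn_in is not None:
            cfg = replace(cfg, burn_in=int(burn_in))
        if seed is not None:
            cfg = replace(cfg, seed=int(seed))
        if overrides:
            cfg = replace(cfg, **overrides)
        cfg = cfg.resolved()
        cfg.validate(self.data.n_times)
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        return _run_chain(self.data, self._cache, cfg, rng, model=self)

    def fit_replicates(self, Q: int = 10, *, seed: int | None = None,
                       **fit_kwargs) -> "ReplicateResults":
        """Q independently seeded runs plus convergence summaries.

        Mirrors the multi-chain convergence protocol: per-run edge scores,
        their elementwise average, and the summed across-run variance.
        """
        if Q < 2:
            raise ValueError("need Q >= 2 replicate runs")
        root = np.random.default_rng(seed)
        seeds = root.integers(2**31 - 1, size=Q)
        runs = [self.fit(seed=int(s), **fit_kwargs) for s in seeds]
        return ReplicateResults(runs=runs, seeds=tuple(int(s) for s in seeds))


@dataclass
class _GeneState:
    pi: frozenset
    V: ChangePointVector
    delta_inv: float
    sigma2_inv: float
    w: list[np.ndarray]
    log_ml: float
    quad_sum: float


def _score(data, cache, cfg, g, pi, V, delta):
    logdet, quad = segment_quadratic_terms(data, g, pi, V, delta, cache)
    n = data.n_times - 1
    A_s, B_s = cfg.hyper.A_sigma, cfg.hyper.B_sigma
    lml = (
        -0.5 * logdet
        + A_s * np.log(B_s)
        - (A_s + n / 2) * np.log(B_s + 0.5 * quad)
        + gammaln(A_s + n / 2)
        - gammaln(A_s)
        - (n / 2) * np.log(2 * np.pi)
    )
    return float(lml), float(quad)


def _gibbs_update(data, cache, cfg, g, state, rng):
    """Algorithm-1 parameter sweep for one gene (collapsed sigma, then w, delta)."""
    delta = 1.0 / state.delta_inv
    state.sigma2_inv = sample_sigma2_inv(
        data, g, state.pi, state.V, delta, cfg.hyper, rng, cache,
        quad_sum=state.quad_sum,
    )
    sigma2 = 1.0 / state.sigma2_inv
    cols = np.asarray([0, *sorted(p + 1 for p in state.pi)], dtype=int)
    ws = []
    for lo, hi in state.V.segments():
        stt = cache.segment_stats(g, cols, lo, hi)
        # draw w from its full conditional using sufficient statistics
        p = len(cols)
        M = np.eye(p) / delta + stt.XtX
        L = np.linalg.cholesky(M)
        u = solve_triangular(L, stt.Xty, lower=True, check_finite=False)
        mean = solve_triangular(L, u, lower=True, trans="T", check_finite=False)
        z = rng.standard_normal(p)
        ws.append(
            mean
            + np.sqrt(sigma2)
            * solve_triangular(L, z, lower=True, trans="T", check_finite=False)
        )
    state.w = ws
    state.delta_inv = sample_delta_inv(ws, sigma2, cfg.hyper, rng)
    state.log_ml, state.quad_sum = _score(
        data, cache, cfg, g, state.pi, state.V, 1.0 / state.delta_inv
    )


def _changepoint_update(data, cache, cfg, g, state, rng, tally):
    j = len(state.V.boundaries)
    b, d, r = cp.move_rates(j, cfg.lambda_K, cfg.K_max)
    u = rng.uniform()
    kw = dict(lam=cfg.lam, lam_K=cfg.lambda_K, K_max=cfg.K_max,
              min_seg_len=cfg.min_seg_len, rng=rng)
    if u < b:
        move = cp.propose_birth(state.V, data, g, **kw)
    elif u < b + d:
        move = cp.propose_death(state.V, data, g, **kw)
    else:
        if j == 0:
            tally[1] += 1
            return  # no boundary to shift: null move, counts as rejected
        move = cp.propose_shift(state.V, min_seg_len=cfg.min_seg_len, rng=rng)
    tally[1] += 1
    if move is None:
        return
    delta = 1.0 / state.delta_inv
    lml_new, quad_new = _score(data, cache, cfg, g, state.pi, move.proposed, delta)
    if cp.accept_changepoint(move, state.log_ml, lml_new, rng):
        state.V = move.proposed
        state.log_ml, state.quad_sum = lml_new, quad_new
        tally[0] += 1


def _structure_update(data, cache, cfg, g, state, F, rng, tally):
    if neighborhood_size(state.pi, g, F.n_genes, cfg.fan_in, cfg.self_loops) == 0:
        tally[1] += 1  # no admissible move (e.g. fan_in 0): null move
        return
    move = propose_structure(
        state.pi, F, g, fan_in=cfg.fan_in, self_loops=cfg.self_loops,
        temperature=cfg.temperature, epsilon=cfg.epsilon, rng=rng,
    )
    tally[1] += 1
    delta = 1.0 / state.delta_inv
    lml_new, quad_new = _score(data, cache, cfg, g, move.proposed, state.V, delta)
    # uniform parent-set prior over |pi| <= fan_in: prior ratio 1
    if accept_structure(move, state.log_ml, lml_new, rng):
        state.pi = move.proposed
        state.log_ml, state.quad_sum = lml_new, quad_new
        tally[0] += 1


def _run_chain(data, cache, cfg, rng, model=None) -> "FCDBNResults":
    G, T = data.n_genes, data.n_times
    states: list[_GeneState] = []
    for g in range(G):
        V = ChangePointVector(T)  # single segment
        pi = frozenset()
        delta_inv = 1.0
        lml, quad = _score(data, cache, cfg, g, pi, V, 1.0 / delta_inv)
        states.append(_GeneState(pi, V, delta_inv, 1.0, [], lml, quad))
    F = FilterMatrix(G)
    Vs = [s.V for s in states]

    I = cfg.iterations
    indicators = np.zeros((I, G, G), dtype=np.uint8)
    boundary_counts = np.zeros((G, T + 1), dtype=np.int64)
    k_counts = np.zeros((G, cfg.K_max + 1), dtype=np.int64)
    acc_cp = np.zeros((G, 2), dtype=np.int64)  # accepted, proposed
    acc_st = np.zeros((G, 2), dtype=np.int64)
    post_sweeps = 0

    for i in range(I):
        for g in range(G):
            _gibbs_update(data, cache, cfg, g, states[g], rng)
        if cfg.K_max > 1:
            for g in range(G):
                _changepoint_update(data, cache, cfg, g, states[g], rng, acc_cp[g])
                Vs[g] = states[g].V
        if cfg.temperature > 0:
            update_filter(F, data, Vs, rng)
        for g in range(G):
            _structure_update(data, cache, cfg, g, states[g], F, rng, acc_st[g])
        for g in range(G):
            if states[g].pi:
                indicators[i, sorted(states[g].pi), g] = 1
        if i >= cfg.burn_in:
            post_sweeps += 1
            for g in range(G):
                k_counts[g, states[g].V.n_segments] += 1
                for bdry in states[g].V.boundaries:
                    boundary_counts[g, bdry] += 1

    trace = EdgeScoreTrace(indicators, cfg.burn_in)
    return FCDBNResults(
        model=model,
        config=cfg,
        trace=trace,
        edge_score_matrix=edge_scores(trace),
        filter_matrix=F,
        changepoint_probability=boundary_counts / max(post_sweeps, 1),
        segment_count_probability=k_counts / max(post_sweeps, 1),
        structure_acceptance=acc_st,
        changepoint_acceptance=acc_cp,
        final_states=states,
    )


@dataclass
class FCDBNResults:
    """Posterior summaries of one MCMC run.

    ``edge_score_matrix[n, j]`` is the posterior inclusion probability of the
    directed edge n -> j; ``changepoint_probability[g, t]`` the post-burn-in
    frequency of a boundary at response time t for gene g.
    """

    model: FCDBN | None
    config: RunConfig
    trace: EdgeScoreTrace
    edge_score_matrix: np.ndarray
    filter_matrix: FilterMatrix
    changepoint_probability: np.ndarray
    segment_count_probability: np.ndarray
    structure_acceptance: np.ndarray  # (G, 2): accepted, proposed
    changepoint_acceptance: np.ndarray
    final_states: list = field(repr=False, default_factory=list)

    @property
    def gene_names(self) -> tuple[str, ...]:
        if self.model is not None:
            return self.model.data.gene_names
        G = self.edge_score_matrix.shape[0]
        return tuple(f"G{i + 1}" for i in range(G))

    def edge_scores_frame(self) -> pd.DataFrame:
        names = self.gene_names
        return pd.DataFrame(self.edge_score_matrix, index=names, columns=names)

    def acceptance_report(self) -> pd.DataFrame:
        """Per-gene and total acceptance counts and ratios (%) per move type."""
        names = list(self.gene_names)
        rows = []
        for label, acc in (
            ("structure", self.structure_acceptance),
            ("changepoint", self.changepoint_acceptance),
        ):
            for g, name in enumerate(names):
                a, p = int(acc[g, 0]), int(acc[g, 1])
                rows.append((label, name, a, p, 100.0 * a / p if p else np.nan))
            a, p = int(acc[:, 0].sum()), int(acc[:, 1].sum())
            rows.append((label, "TOTAL", a, p, 100.0 * a / p if p else np.nan))
        return pd.DataFrame(
            rows, columns=["move", "gene", "accepted", "proposed", "ratio_pct"]
        )

    def evaluate(self, gold: set[tuple[int, int]]):
        """PR metrics of the edge scores against a gold-standard edge set."""
        return pr_metrics(
            self.edge_score_matrix, gold, self_loops=self.config.self_loops
        )

    def summary(self, top: int = 10) -> str:
        names = self.gene_names
        G = len(names)
        scores = self.edge_score_matrix
        pairs = sorted(
            (
                (scores[i, j], names[i], names[j])
                for i in range(G)
                for j in range(G)
                if self.config.self_loops or i != j
            ),
            reverse=True,
        )[:top]
        acc = self.acceptance_report()
        st_tot = acc[(acc.move == "structure") & (acc.gene == "TOTAL")].iloc[0]
        cp_tot = acc[(acc.move == "changepoint") & (acc.gene == "TOTAL")].iloc[0]
        mean_k = (
            self.segment_count_probability
            * np.arange(self.segment_count_probability.shape[1])
        ).sum(axis=1)
        lines = [
            "FC-DBN results",
            "==============",
            f"genes: {G}",
            f"iterations: {self.config.iterations}   burn-in: {self.config.burn_in}",
            f"structure acceptance:   {st_tot.accepted}/{st_tot.proposed} ({st_tot.ratio_pct:.1f}%)",
            f"changepoint acceptance: {cp_tot.accepted}/{cp_tot.proposed} ({cp_tot.ratio_pct:.1f}%)",
            "",
            "posterior mean segments per gene:",
            "  " + "  ".join(f"{n}:{k:.2f}" for n, k in zip(names, mean_k)),
            "",
            f"top {len(pairs)} edges by posterior inclusion probability:",
        ]
        for s, a, b in pairs:
            lines.append(f"  {a:>8s} -> {b:<8s} {s:.3f}")
        return "\n".join(lines)

    def plot_pr(self, gold, ax=None):
        import matplotlib.pyplot as plt

        res = self.evaluate(gold)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(res.recall, res.precision, marker="o")
        ax.set_xlabel("recall")
        ax.set_ylabel("precision")
        ax.set_title(f"AUC-PR = {res.auc_pr:.3f}")
        return ax


@dataclass
class ReplicateResults:
    """Q independently seeded runs and their convergence summaries."""

    runs: list[FCDBNResults]
    seeds: tuple[int, ...]

    @property
    def per_run_scores(self) -> list[np.ndarray]:
        return [r.edge_score_matrix for r in self.runs]

    @property
    def average_scores(self) -> np.ndarray:
        return average_edge_scores(self.per_run_scores)

    @property
    def variance_sum(self) -> float:
        return edge_score_variance(self.per_run_scores)

    def scatter_data(self) -> pd.DataFrame:
        """Per-edge (run, edge score, average score) pairs: the y=x diagnostic."""
        avg = self.average_scores
        names = self.runs[0].gene_names
        G = len(names)
        rows = []
        for q, m in enumerate(self.per_run_scores):
            for i in range(G):
                for j in range(G):
                    if i == j and not self.runs[0].config.self_loops:
                        continue
                    rows.append((q, names[i], names[j], m[i, j], avg[i, j]))
        return pd.DataFrame(
            rows, columns=["run", "source", "target", "edge_score", "average_score"]
        )

    def plot_convergence(self, ax=None):
        import matplotlib.pyplot as plt

        df = self.scatter_data()
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(df.edge_score, df.average_score, s=8, alpha=0.5)
        ax.plot([0, 1], [0, 1], "k--", lw=1)
        ax.set_xlabel("edge score (single run)")
        ax.set_ylabel("average edge score")
        return ax

    def summary(self) -> str:
        return (
            f"{len(self.runs)} replicate chains\n"
            f"summed edge-score variance: {self.variance_sum:.4g}"
        )
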