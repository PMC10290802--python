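# Methods

## Model

`fcdbn` fits a nonhomogeneous dynamic Bayesian network to a short
gene-expression time series `D` (G genes × T time points).  Each gene g
follows a lag-1 linear-Gaussian regression whose coefficients are allowed to
change across time segments:

    y_g(t) = [1, x_{π_g}(t−1)] · w_{g,k} + ε,    ε ~ N(0, σ_g²),

where π_g is gene g's parent set (|π_g| ≤ fan-in), k is the segment of a
per-gene change-point vector V_g covering response time t, and the intercept
is always included.  Response times are t = 2..T (a lag-1 model loses the
first point); all segmentations are expressed in these coordinates.

The parameter hierarchy is fully conjugate:

    w_{g,k} | σ_g², δ_g  ~  N(0, δ_g σ_g² I)
    δ_g⁻¹               ~  Gamma(A_δ, B_δ)
    σ_g⁻²               ~  Gamma(A_σ, B_σ)

so w and σ² integrate out in closed form.  The collapsed marginal
P(y_g | X, δ_g) — a multivariate-t-type expression with per-segment
log-determinant terms and one shared quadratic rate — is the score used by
both the structure and the change-point samplers; because every
dimension-changing parameter is integrated out, the reversible-jump moves
need no Jacobian.  δ_g is gene-specific, matching the per-gene subscripts of
the hierarchy.

## Sampler

One sweep performs, in order:

1. **Parameter Gibbs** per gene: σ_g⁻² from its collapsed conditional
   (shape A_σ + (T−1)/2; the (T−1) counts response times regardless of
   segmentation), segment coefficients w_{g,k} from their Gaussian
   conditionals, then δ_g⁻¹ from its Gamma conditional with shape
   A_δ + K_g(|π_g|+1)/2.
2. **Change-point RJ-MCMC** per gene: one birth / death / shift move.
3. **Filter update** (skipped entirely at temperature 0).
4. **Structure Metropolis–Hastings** per gene: one add/remove move on π_g.

### Manhattan-distance birth

A birth location τ is drawn with probability ∝ exp(d(τ)), where

    d(τ) = λ (|var(left) − var(right)| + |mean(left) − mean(right)|)

is computed from the target gene's own values on the would-be sub-segments
(population variance).  The exponential weighting keeps every admissible
location proposable when d = 0; λ = 0 recovers the uniform, distance-blind
birth.  One subtlety worth knowing: for a clean step of height J, d is
maximized *exactly at* the step only when J is moderate relative to the
(standardized) scale — for large J an off-center split gains mixture
variance that can outweigh the mean term.  This only shapes proposals; the
acceptance ratio carries the exact forward/reverse probabilities, so the
posterior is untouched.

Death deletes a uniformly chosen boundary (its reverse probability is the
matched birth's); the shift move slides a boundary one step left or right
and is symmetric.  Move-kind rates follow the standard schedule
b_j = c·min(1, p(j+1)/p(j)), d_j = c·min(1, p(j−1)/p(j)), r_j the
remainder, with c = 0.4 and p a Poisson(λ_K) prior on the number of change
points truncated at K_max segments.  The prior over V_g is that Poisson on
the count times a uniform over admissible configurations given the count
(counted as compositions of T−1 response times into segments ≥ min_seg_len).

### Correlation filter

Whole-series Pearson correlation is unreliable on non-stationary series, so
the filter accumulates correlations segment-wise: per sweep and target gene
one segment is drawn with probability proportional to its length and its
correlation with each other gene over the same time span is folded into a
running matrix R by

    R ← (R·C + P·w) / (C + w),   C ← C + w,   w = |segment| / T.

C is maintained per ordered gene pair: a pair whose update is skipped
(constant segment, undefined correlation) must not corrupt the convex
combination for other pairs.  When the span straddles several segments of
the other gene, each overlap of length ≥ 2 contributes its own correlation
weighted by overlap length.  Two consequences follow directly from the
recursion: longer segments are both selected more often and weighted more,
and the n-th update's weight on the new observation, w/(C₀ + n·w), decays —
early sweeps shape R, late sweeps refine it.

R biases only the parent-addition proposal: candidate g′ is drawn with
probability ∝ (|R[g,g′]| + ε)^temperature.  The absolute value treats
strong repression as informative as activation; ε > 0 keeps every candidate
reachable.  Proposal neighbors are weighted so that removals carry unit
weight and additions carry n_add × (normalized filter weight): at
temperature 0 this is exactly the uniform draw over the one-edit
neighborhood S(π), and the acceptance ratio reduces to the classical
|S(π)|/|S(π′)| Hastings correction.  At any temperature the exact forward
and reverse proposal probabilities enter the acceptance ratio, so the filter
can never shift the stationary distribution — this is checked against
brute-force-enumerated posteriors in the test suite.  The parent-set prior
is uniform over all sets with |π| ≤ fan-in, so its ratio cancels.

## Defaults and units

| parameter | default | meaning |
|---|---|---|
| fan_in | 3 | max parents per gene |
| K_max | 10 | max segments per gene |
| min_seg_len | max(2, fan_in + 2) | shortest admissible segment (time points), so each segment supports its regression |
| λ (lam) | 1.0 | Manhattan-distance birth scale (dimensionless on standardized data) |
| temperature | 1.0 | filter bias strength; 0 = uniform baseline |
| ε (epsilon) | 0.01 | proposal floor for unseen candidates |
| λ_K (lambda_K) | 1.0 | Poisson prior mean, change points per gene |
| A_δ, B_δ | 2, 0.2 | weak prior, E[δ⁻¹] = 10 (coefficients shrink mildly) |
| A_σ, B_σ | 0.005, 0.005 | near-Jeffreys noise prior |
| burn_in | iterations/2 | discarded sweeps |
| standardize | on | per-gene z-scoring at run start |

Expression values are z-standardized per gene by default: the correlation
filter and the signal-to-noise prior both assume comparable scales, and the
raw loader never modifies data (standardization is an explicit, reversible
model choice, not an I/O side effect).

## Synthetic benchmarks

The simulator generates data from the model's own generative family:
piecewise lag-1 linear-Gaussian dynamics with known topology, per-segment
coefficients (sign-flipping across segments by default, so regimes differ
in both mean and variance structure and both terms of d(τ) are exercised),
Gaussian observation noise, a N(0,1) initial state and 10 discarded warm-up
steps.  Presets: a 5-gene × 35-point cyclic network with one change point
per gene and coefficient magnitude 0.9 at noise sd 0.1; an 11-node
signalling cascade using the 20-edge consensus RAF-pathway topology
(synthetic coefficients) over two regimes, T = 50; and a null network.
Both topologies are synthetic stand-ins of the same size and density as the
classic benchmarks in this literature.

What passing the recovery tests does *not* show: real expression data are
not generated by a linear-Gaussian lag-1 process, have measurement noise
that is neither Gaussian nor homoscedastic, and hide latent regulators.
Recovery of the simulated truth demonstrates correctness of the inference
machinery (the samplers target the right posterior and the posterior
concentrates where the model family matches the data), not field
performance on microarray or qPCR series.

## Numerical choices

* All likelihood work is in log space; per-segment Gram matrices come from
  prefix-sum cross products (segments are contiguous response-time ranges),
  and (I + δXᵀX) is handled by Cholesky factorization with the Woodbury
  identity for the quadratic form — no explicit inverses.
* Pearson correlations use population normalization and return 0 for a
  constant vector (no evidence rather than NaN).
* Non-finite acceptance ratios reject (with a warning for NaN in the
  structure move); a proposed −∞ marginal is never accepted.
* Degenerate inputs: a gene with no admissible structure move (fan_in 0 on
  a 2-gene problem) or no boundary to shift counts the sweep's move as
  proposed-and-rejected, keeping acceptance accounting comparable across
  configurations.
* Problem sizes in the checked-in tests (3-gene enumeration chains at
  2×10⁵ sweeps, 5 recovery runs at 2×10⁴ sweeps, T = 8 change-point
  enumeration) were chosen as the smallest sizes at which the enumerated
  posteriors and recovery rates are stable across seeds.

## Known limitations

* Cost per sweep grows with G² (filter update) and with the number of
  admissible birth locations; the design targets small networks (≤ ~20
  genes), like the family of models it belongs to.
* Change points are per-gene and independent; globally shared regime
  switches are modeled only implicitly.
* The segment-wise correlation pairs same-time spans; lagged correlation
  might bias proposals better for strongly delayed regulation.
* The uniform parent-set prior is not size-penalizing beyond the fan-in
  cap; sparsity comes from the marginal likelihood's Occam factor alone.
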