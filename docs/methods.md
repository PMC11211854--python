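# Methods

## Model

For a ligand–receptor pair and a directed spatial adjacency graph
G = (V, E) over spots, the observed pairs {(ℓᵢ, rⱼ)}_{(i,j)∈E} are modeled
as draws from a bivariate distribution with

- Poisson marginals ℓᵢ ~ Pois(Nᵢ e^{μ_ℓ}) and rⱼ ~ Pois(Nⱼ e^{μ_r}), where
  Nᵢ is the spot's total UMI count (full-matrix row sum). The offset makes
  μ a log *normalized* mean expression and absorbs depth variation — two
  unrelated genes correlate in raw counts simply because both scale with
  Nᵢ, and the offset removes exactly that confounder;
- a Gaussian copula with covariance Σ_ρ = [[1, ρ], [ρ, 1]]; the joint
  density factorizes as c_ρ(F_L(ℓᵢ), F_R(rⱼ)) · P(ℓᵢ) · P(rⱼ), with

  log c_ρ(u, v) = −½ log(1 − ρ²) − [ρ²(z₁² + z₂²) − 2ρz₁z₂] / (2(1 − ρ²)),
  z = Φ⁻¹(·).

The copula correlation ρ is the interaction score. The log-likelihood sums
the three terms over directed edges, so a spot contributes once per
incident edge; marginal MLEs therefore carry per-vertex edge multiplicities
(a de-duplicated variant is available via `dedup_multiplicity` for
sensitivity analysis).

### Distributional transform

Copula decompositions of discrete distributions are not unique. We smooth
each Poisson CDF with the deterministic midpoint transform
u = (F(x−1) + F(x))/2, which is strictly inside (0, 1), monotone in the
count, and — unlike the randomized transform — yields a deterministic,
reproducible likelihood. On ≤10-edge fixtures the resulting likelihood
tracks the exact rectangle-probability likelihood (copula CDF differenced
at the four corners of each count cell) to within ~0.1 log-units over
|ρ| ≤ 0.6 at moderate rates, with coinciding maximizers (tested).

### Estimation

Two stages:

1. μ̂_ℓ, μ̂_r in closed form: exp(μ̂) = Σ(m·counts)/Σ(m·depths) with edge
   multiplicities m (the Poisson MLE with offsets, which is also the joint
   MLE at ρ = 0, where the copula term vanishes).
2. ρ̂ by bounded derivative-free (Brent-class) maximization of the profile
   log-likelihood over ρ ∈ [−1+ε, 1−ε], ε = 10⁻⁴ (the clamp keeps Σ_ρ
   nonsingular), tolerance 10⁻⁶, ties broken toward ρ = 0. Given the
   per-vertex Gaussian scores, the copula term depends on the data only
   through (|E|, Σz₁², Σz₂², Σz₁z₂), so each likelihood evaluation is O(1)
   after one O(|E|) gather — this is what makes the permutation test cheap.

An optional Nelder–Mead refinement of all three parameters from the
two-stage optimum is exposed (`joint_refine`) but off by default: on
simulated data the two-stage estimate is already at the joint optimum to
within the optimizer tolerance.

### Likelihood-shape screen

Very sparse pairs can have multi-modal profile likelihoods, making ρ̂
unstable. The screen evaluates f(ρ) on a 201-point equispaced grid with
μ's fixed at their ρ = 0 MLEs and takes second differences. The default
mode keeps a pair only when f is strictly concave everywhere (every second
difference < 0). A `literal` mode with the opposite polarity — exclude
whenever any second difference is ≤ 0 — is provided for comparison; note
that polarity excludes every well-behaved concave profile, so `default` is
the recommended setting. Whether concavity is assessed analytically or
numerically is an implementation freedom; the 201-point central-stencil
second difference is cheap and derivative-free.

Pairs whose ligand or receptor is all-zero over edge-incident spots are
flagged `degenerate` before the screen is reached.

## Significance

The null hypothesis is that spots are randomly arranged in the tissue: a
uniform vertex permutation π gives G′ with edges {(π(i), π(j))}, ρ is
re-estimated on G′, and p = #{|ρ̂_{G′}| > |ρ̂|}/n_perm (a pseudocount mode
(1+#)/(1+n) is available; fraction-mode p = 0 should be reported as
"< 1/n_perm"). For cell-type-specific questions the permutation fixes all
vertices outside the two cell types. Benjamini–Hochberg adjusts across
pairs; the conventional FDR < 0.2 call is a report annotation, not a
filter. Defaults: n_perm = 500.

Permutation refits hold μ̂'s at their observed values. Re-estimating them
per permutation would change nothing at leading order (the edge multiset
and hence the multiplicity-weighted totals are permuted versions of the
same values) while multiplying cost; a `full_refit` mode exists for
checking this. Under the fixed-μ scheme each permutation costs one O(|E|)
gather plus an O(1)-per-evaluation maximization.

Two structural caveats, both verified empirically during development:

- **Self-loops are fixed points of the null.** π maps (i, i) to
  (π(i), π(i)), which still pairs a spot with itself, so same-spot
  correlation survives into the null distribution. On a self-loop-only
  graph the permutation test is fully degenerate (every ρ̂_{G′} equals ρ̂);
  on mixed graphs it is conservative for correlations driven mainly by
  same-spot co-expression. Interaction signals carried across neighbor
  edges are tested with full power.
- p-values are discrete (multiples of 1/n_perm); calibration tests use KS
  against uniform, which tolerates this granularity at n_perm ≥ 200.

## Interaction scores

For each directed edge (i, j), z = [Φ⁻¹(DT(ℓᵢ)), Φ⁻¹(DT(rⱼ))] under the
fitted marginals, and the score is the Mahalanobis form
zᵀΣ̂⁻¹z = (z₁² + z₂² − 2ρ̂z₁z₂)/(1 − ρ̂²). Large scores mark edges where
ligand and receptor deviate jointly from their means — candidate
interaction sites. The edge direction encodes ligand → receptor. For
map-style visualization a per-spot reduction over incident edges is
provided; `max` is the default (a spot participating in any extreme edge is
highlighted), with `mean` and `sum` as configurable alternatives since no
canonical reduction exists.

## Baselines

`generalized_pearson` implements the edge-weighted cross-correlation in
three parameterizations: `meringue` (unweighted Delaunay adjacency,
c = N/|E|; duplicate coordinates are jittered by 10⁻⁹ so the triangulation
is defined), `spatialdm` (complete graph, w_ij ∝ exp(−d²_ij/σ²) scaled so
max w = 1 — any global constant is absorbed by c; σ is dataset-dependent
and required, no silent default), and `plain` (c = 1, unit weights; on a
self-loop-only graph this is the textbook Pearson coefficient, verified to
10⁻¹²). Log-normalization is log(1 + count·target_sum/Nᵢ) with target_sum
defaulting to the median depth. Only the baselines' correlation statistics
are reproduced, not their analytic significance machinery.

## Simulator

`sample_copula_counts` draws (z₁, z₂) from the bivariate Gaussian, maps
u = Φ(z), and inverts the Poisson CDF at rates k·Nᵢ·e^μ. Defaults, chosen
once as a realistic Visium-scale regime and fixed:

- depths Nᵢ: log-normal (meanlog 9, sdlog 0.5), rounded, ≥ 1 — median
  ≈ 8100 total UMI per spot with realistic dispersion; a real depth vector
  can be supplied instead;
- μ_ℓ = μ_r = −8: per-spot rate ≈ 2.7 at k = 1, a well-expressed
  ligand/receptor scale;
- k per sparsity bucket (<10%, 10–30%, >30% zeros) found by bisection on
  the expected zero fraction mean_i exp(−k·Nᵢ·e^μ), targeting 0.05 / 0.20 /
  0.60 — bucket membership, not any particular k value, is what matters.

The benchmark (n = 500 per dataset, 50 replicates per cell, ρ ∈ {−0.8,
−0.4, 0, 0.4, 0.8} × three buckets) fits each estimator on a self-loop-only
graph — each sample pair is one edge, a non-spatial design — and records
ρ̂ − ρ. These problem sizes run the whole benchmark in seconds while giving
standard errors of ~0.005 on mean bias.

`simulate_spatial_dataset` plants one correlated pair among independent
null pairs on an n×n grid. The planted ligand and receptor share a
spatially smooth latent field (iid Gaussians averaged over the
4-neighborhood, 3 rounds, re-standardized), giving an adjacent-spot field
correlation of ~0.8 so the nominal ρ is carried across neighbor edges at
close to its stated value (~0.55 edge-level for ρ = 0.7) rather than being
a same-spot-only effect. Null genes are iid across spots — note their raw
counts still correlate through shared depths, which is precisely the
confounder the offset marginals absorb.

What the simulator does **not** emulate: overdispersion beyond Poisson
(negative-binomial marginals), spatially varying mean expression,
segmentation errors, multi-cell-type spot mixtures, and spatial correlation
in null genes. Passing benchmarks therefore demonstrate correctness of the
estimator under its own generative assumptions and its robustness to
sparsity and depth variation, not robustness to every artifact of real
tissue data.

## Results ranking

In the output table, copula results are ranked by (q, p, −|ρ̂|): among
pairs tied at the same discrete permutation p-value, the stronger estimated
correlation ranks first.

## Known limitations

- Poisson marginals understate biological overdispersion; a
  negative-binomial extension would change the marginal CDFs only.
- The permutation null assumes exchangeability of spots (within cell type
  when restricted); strong spatial expression gradients violate it and can
  inflate significance for both the copula statistic and the baselines.
- Heteromeric complex expression is the subunit sum; when subunits are
  missing from the matrix the default policy sums the present ones with a
  warning (`strict` drops the pair) — the right choice is data-dependent.
- Expression-prevalence filtering defaults to 10% of spots; published
  pipelines use a fixed spot count that varies by dataset, so the threshold
  is exposed as configuration.
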