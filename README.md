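# copulacci

Count-based inference of ligand–receptor cell–cell interactions in
spatially resolved transcriptomics (SRT), using a bivariate Gaussian copula
with Poisson marginals.

## The problem

SRT assays (10x Visium, Stereo-seq, seqFISH+) measure UMI counts per gene at
spatially located spots. A cell–cell interaction mediated by a ligand *L*
and receptor *R* should leave a statistical footprint: across spatially
adjacent spots (i, j), the ligand count ℓᵢ and receptor count rⱼ co-vary.
Most tools quantify this with an edge-weighted ("generalized Pearson" /
bivariate Moran's I) correlation

```
ρ_spatial = c · Σ_{(i,j)∈E} w_ij (ℓᵢ − ℓ̄)(rⱼ − r̄)
            / √( Σᵢ(ℓᵢ − ℓ̄)² · Σⱼ(rⱼ − r̄)² )
```

which is badly attenuated when counts are sparse — the norm for
ligand/receptor genes. This package instead models the **joint count
distribution** directly:

- marginals ℓᵢ ~ Pois(Nᵢ e^{μ_ℓ}), rⱼ ~ Pois(Nⱼ e^{μ_r}), with Nᵢ the
  spot's total UMI count acting as an exposure offset;
- dependence through a bivariate Gaussian copula with correlation ρ, made
  identifiable for discrete marginals via the midpoint distributional
  transform u = (F(x−1) + F(x))/2;
- the MLE ρ̂ over all directed edges of the spatial adjacency graph (with
  self-loops for autocrine signaling) is the interaction score;
- significance by a spot-permutation null with Benjamini–Hochberg FDR
  control, optionally restricted to two cell types;
- per-edge Mahalanobis scores zᵀΣ̂⁻¹z localize where in the tissue the
  interaction occurs.

Baselines (plain Pearson/Spearman on log-normalized counts, MERINGUE-style
Delaunay cross-correlation, SpatialDM-style Gaussian-kernel statistic) are
included for comparison, and a simulator draws data from the generative
model for validation.

## Worked example

Simulate 500 sparse ligand–receptor count pairs with true copula
correlation ρ = 0.6, then fit:

```python
from copulacci import (SimConfig, sample_copula_counts, selfloop_graph,
                       fit_copula)
from copulacci.baselines import log_normalize_vector, naive_correlations

cfg = SimConfig(n_samples=500, rho=0.6, k=0.2, seed=7)   # k: sparsity dial
l, r, depths = sample_copula_counts(cfg)
print((l == 0).mean())                                    # 0.612 zeros

fit = fit_copula(selfloop_graph(500), l, r, depths)
print(f"rho_hat = {fit.rho:.3f}")                         # rho_hat = 0.561

x, y = log_normalize_vector(l, depths), log_normalize_vector(r, depths)
pear, spear = naive_correlations(x, y)
print(f"{pear:.3f} {spear:.3f}")                          # 0.315 0.343
```

With 60% zeros the copula estimate (0.561) sits close to the true 0.6,
while Pearson and Spearman on log-normalized counts collapse to ~0.3 —
the attenuation the model is designed to avoid.

The full pipeline runs from the shell on a count matrix, a coordinate
table, and a ligand–receptor pair TSV:

```sh
copulacci run --matrix counts.csv --coords coords.csv --lrdb pairs.tsv \
    --layout hex --spacing 100 --n-perm 500 --seed 1 --out results/
```

writing `pair_results.tsv` (one row per pair per method with ρ̂, permutation
p, BH q), per-pair edge-score tables for significant pairs, and a run log.
`copulacci simulate`, `copulacci graph`, and `copulacci score` expose the
simulator, graph export, and single-pair scoring.

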