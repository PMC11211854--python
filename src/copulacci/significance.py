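"""Permutation significance for the copula correlation and BH FDR control.

The null model randomly rearranges spots in the tissue: a uniform vertex
permutation pi of the spatial adjacency graph produces G' with edges
{(pi(i), pi(j))}, the copula correlation is re-estimated on G', and the
p-value is the fraction of permuted graphs whose |rho'| exceeds the
observed |rho|.  For cell-type-specific questions only spots of the two
cell types are permuted.  Benjamini-Hochberg adjusts across pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from . import copula as _cop
from .graph import SpatialGraph, random_vertex_permutation

logger = logging.getLogger(__name__)

__all__ = ["PairResult", "permutation_pvalue", "bh_adjust"]


@dataclass
class PairResult:
    """Per ligand-receptor pair outcome of one method."""

    pair_id: str
    method: str  # copulacci | meringue | spatialdm | pearson | spearman
    rho_hat: float
    p_value: float
    q_value: float
    n_edges: int
    n_permutations: int
    sparsity_ligand: float
    sparsity_receptor: float
    screened: bool = False
    screen_reason: str = "none"


def permutation_pvalue(
    g: SpatialGraph,
    l,
    r,
    depths,
    rho_obs: float,
    n_perm: int = 500,
    seed: int | np.random.Generator = 0,
    restrict_to=None,
    mu_l: float | None = None,
    mu_r: float | None = None,
    pseudocount: bool = False,
    full_refit: bool = False,
) -> tuple[float, np.ndarray]:
    """Permutation p-value for an observed copula correlation.

    For each permuted graph the correlation is re-estimated with the
    marginal means held at their observed MLEs (``full_refit=True``
    re-estimates them per permutation instead).  Fraction mode reports
    #{|rho'| > |rho_obs|} / n_used; ``pseudocount`` mode reports
    (1 + #) / (1 + n_used).  Degenerate refits are dropped with a logged
    count; if more than half drop the p-value is returned as ``nan``.

    Returns (p, null_samples) with the retained null correlations.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    l = np.asarray(l)
    r = np.asarray(r)
    depths = np.asarray(depths, dtype=float)

    if mu_l is None or mu_r is None:
        mult_src, mult_tgt = _cop.edge_multiplicities(g)
        mu_l = _cop.fit_marginal_mu(l, depths, mult_src) if mu_l is None else mu_l
        mu_r = _cop.fit_marginal_mu(r, depths, mult_tgt) if mu_r is None else mu_r
    z_l = _cop.gaussian_scores(l, depths, mu_l)
    z_r = _cop.gaussian_scores(r, depths, mu_r)

    src, tgt = g.sources, g.targets
    null = np.empty(n_perm)
    dropped = 0
    for b in range(n_perm):
        perm = random_vertex_permutation(g.n_vertices, rng, restrict_to)
        ps, pt = perm[src], perm[tgt]
        if full_refit:
            gp = SpatialGraph(g.n_vertices, np.column_stack([ps, pt]))
            fit = _cop.fit_copula(gp, l, r, depths)
            if fit.screen_reason == "degenerate":
                null[b] = np.nan
                dropped += 1
                continue
            null[b] = fit.rho
        else:
            z1 = z_l[ps]
            z2 = z_r[pt]
            # unidentifiable when either side has no variation across edges
            if np.ptp(z1) == 0 or np.ptp(z2) == 0:
                null[b] = np.nan
                dropped += 1
                continue
            m = z1.size
            rho_b, _ = _cop.profile_rho_mle(
                m, float(z1 @ z1), float(z2 @ z2), float(z1 @ z2)
            )
            null[b] = rho_b

    if dropped:
        logger.info("dropped %d/%d degenerate permutation refits", dropped, n_perm)
    kept = null[np.isfinite(null)]
    n_used = kept.size
    if n_used < n_perm / 2:
        logger.warning("more than 50%% of permutation refits degenerate; p unreliable")
        return float("nan"), kept
    n_exceed = int((np.abs(kept) > abs(rho_obs)).sum())
    if pseudocount:
        p = (1 + n_exceed) / (1 + n_used)
    else:
        p = n_exceed / n_used
    return float(p), kept


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    q_(i) = min_{k >= i} p_(k) * m / k, clipped at 1.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any((pvals < 0) | (pvals > 1) | ~np.isfinite(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]
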