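"""Per-edge Mahalanobis interaction scores.

After fitting the copula model, each directed edge (i, j) gets a score
measuring how far the transformed ligand/receptor pair lies from the center
of the fitted bivariate Gaussian:

    z = [Phi^{-1}(DT(l_i; N_i e^{mu_l})), Phi^{-1}(DT(r_j; N_j e^{mu_r}))]
    score = z^T Sigma_rho^{-1} z
          = (z_l^2 + z_r^2 - 2 rho z_l z_r) / (1 - rho^2).

Large scores localize where in the tissue the ligand and receptor deviate
jointly from their means — candidate interaction sites.  The edge direction
encodes ligand -> receptor orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .copula import CopulaFit, gaussian_scores
from .graph import SpatialGraph

__all__ = ["EdgeScore", "edge_scores", "mahalanobis_score", "spot_summary"]


@dataclass(frozen=True)
class EdgeScore:
    edge: tuple[int, int]
    z_l: float
    z_r: float
    score: float


def mahalanobis_score(z_l, z_r, rho: float) -> np.ndarray | float:
    """Quadratic form z^T Sigma_rho^{-1} z for Sigma_rho = [[1, rho], [rho, 1]]."""
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    z_l = np.asarray(z_l, dtype=float)
    z_r = np.asarray(z_r, dtype=float)
    out = (z_l**2 + z_r**2 - 2.0 * rho * z_l * z_r) / (1.0 - rho**2)
    return out if out.ndim else float(out)


def edge_scores(g: SpatialGraph, l, r, depths, fit: CopulaFit) -> list[EdgeScore]:
    """Mahalanobis interaction score for every directed edge of the graph."""
    if fit.screened_out:
        raise ValueError("fit was screened out; scores are not meaningful")
    z_l = gaussian_scores(l, depths, fit.params.mu_l)
    z_r = gaussian_scores(r, depths, fit.params.mu_r)
    z1 = z_l[g.sources]
    z2 = z_r[g.targets]
    s = mahalanobis_score(z1, z2, fit.params.rho)
    return [
        EdgeScore((int(i), int(j)), float(a), float(b), float(sc))
        for (i, j), a, b, sc in zip(g.edges, z1, z2, s)
    ]


def spot_summary(
    g: SpatialGraph, scores: list[EdgeScore], reduction: str = "max"
) -> np.ndarray:
    """Reduce edge scores to one value per spot for map-style visualization.

    A spot's summary aggregates the scores of all its incident edges
    (either endpoint); ``reduction`` is one of max, mean, sum.  Spots with
    no incident edge get 0.
    """
    if reduction not in ("max", "mean", "sum"):
        raise ValueError(f"unknown reduction {reduction!r}")
    acc: list[list[float]] = [[] for _ in range(g.n_vertices)]
    for es in scores:
        i, j = es.edge
        acc[i].append(es.score)
        if j != i:
            acc[j].append(es.score)
    out = np.zeros(g.n_vertices)
    for v, vals in enumerate(acc):
        if not vals:
            continue
        if reduction == "max":
            out[v] = max(vals)
        elif reduction == "mean":
            out[v] = float(np.mean(vals))
        else:
            out[v] = float(np.sum(vals))
    return out
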