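"""Reference correlation measures for the interaction-inference problem.

The generalized Pearson correlation (an edge-weighted cross-covariance over
the spatial graph, a bivariate Moran's-I-style statistic)

    rho_spatial = c * sum_{(i,j) in E} w_ij (l_i - lbar)(r_j - rbar)
                  / sqrt( sum_i (l_i - lbar)^2 * sum_j (r_j - rbar)^2 )

covers both MERINGUE's spatial cross-correlation (unweighted Delaunay
adjacency, c = N / |E|) and SpatialDM's global statistic (complete graph,
Gaussian kernel weights w_ij ∝ exp(-d_ij^2 / sigma^2), c = 1).  With c = 1,
unit weights and a self-loop-only graph it reduces to the plain Pearson
correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import Delaunay

from .graph import SpatialGraph
from .lrdb import CountMatrix

__all__ = [
    "BaselineConfig",
    "generalized_pearson",
    "log_normalize",
    "naive_correlations",
]


@dataclass
class BaselineConfig:
    """Parameterization of the generalized Pearson correlation.

    ``scheme='meringue'`` uses an unweighted Delaunay graph with
    c = N / |E|; ``scheme='spatialdm'`` uses a complete graph with Gaussian
    weights of length scale ``sigma`` (required, dataset-dependent) and
    c = 1; ``scheme='plain'`` uses the supplied graph with c and unit
    weights (self-loop-only graph -> textbook Pearson).
    """

    scheme: str = "plain"
    c: float | None = None
    sigma: float | None = None
    graph_source: str = "given"

    def __post_init__(self) -> None:
        if self.scheme not in ("meringue", "spatialdm", "plain"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "spatialdm" and (self.sigma is None or self.sigma <= 0):
            raise ValueError("spatialdm scheme requires sigma > 0")
        if self.c is not None and self.c <= 0:
            raise ValueError("c must be positive")


def _delaunay_edges(coords: np.ndarray) -> np.ndarray:
    """Directed edge list of the Delaunay triangulation; duplicate points
    are jittered infinitesimally so the triangulation is defined."""
    coords = np.asarray(coords, dtype=float)
    uniq = np.unique(coords, axis=0)
    if uniq.shape[0] < coords.shape[0]:
        rng = np.random.default_rng(0)
        coords = coords + rng.normal(scale=1e-9, size=coords.shape)
    tri = Delaunay(coords)
    pairs = set()
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                i, j = int(simplex[a]), int(simplex[b])
                pairs.add((i, j))
                pairs.add((j, i))
    return np.array(sorted(pairs), dtype=np.int64)


def _complete_gaussian(coords: np.ndarray, sigma: float):
    """All ordered pairs (i != j) with max-normalized Gaussian weights."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1)
    w = np.exp(-d2 / sigma**2)
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    off = ii != jj
    edges = np.column_stack([ii[off], jj[off]]).astype(np.int64)
    weights = w[off]
    return edges, weights / weights.max()


def generalized_pearson(g: SpatialGraph, l, r, cfg: BaselineConfig) -> float:
    """Edge-weighted cross-correlation over the spatial graph.

    Returns ``nan`` when either vector has zero variance.
    """
    l = np.asarray(l, dtype=float)
    r = np.asarray(r, dtype=float)
    if cfg.scheme == "meringue":
        if g.coords is None:
            raise ValueError("meringue scheme needs coordinates")
        edges = _delaunay_edges(g.coords)
        weights = np.ones(edges.shape[0])
        c = cfg.c if cfg.c is not None else g.n_vertices / edges.shape[0]
    elif cfg.scheme == "spatialdm":
        if g.coords is None:
            raise ValueError("spatialdm scheme needs coordinates")
        edges, weights = _complete_gaussian(g.coords, cfg.sigma)
        c = cfg.c if cfg.c is not None else 1.0
    else:
        edges = g.edges
        weights = g.weights if g.weights is not None else np.ones(g.n_edges)
        c = cfg.c if cfg.c is not None else 1.0

    dl = l - l.mean()
    dr = r - r.mean()
    denom = np.sqrt((dl**2).sum() * (dr**2).sum())
    if denom == 0:
        return float("nan")
    num = float(np.sum(weights * dl[edges[:, 0]] * dr[edges[:, 1]]))
    return c * num / denom


def log_normalize(m: CountMatrix, target_sum: float | None = None) -> np.ndarray:
    """Depth-normalized log counts: log(1 + count * target_sum / N_i).

    ``target_sum`` defaults to the median spot depth.  Zeros map to zeros
    and the transform is monotone within each spot.
    """
    if target_sum is None:
        target_sum = float(np.median(m.depths))
    scaled = m.counts * (target_sum / m.depths[:, None])
    return np.log1p(scaled)


def log_normalize_vector(counts, depths, target_sum: float | None = None) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    depths = np.asarray(depths, dtype=float)
    if target_sum is None:
        target_sum = float(np.median(depths))
    return np.log1p(counts * target_sum / depths)


def naive_correlations(x, y) -> tuple[float, float]:
    """(Pearson, Spearman) correlation of paired samples; Spearman uses
    mid-ranks for ties.  Constant input yields (nan, nan)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("inputs must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    pearson = float(stats.pearsonr(x, y).statistic)
    spearman = float(stats.spearmanr(x, y).statistic)
    return pearson, spearman
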