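"""Spatial adjacency graphs over spots.

The spatial adjacency graph G = (V, E) is directed: edge (i, j) means a
ligand expressed at spot i may bind a receptor at spot j.  Grid and radius
constructions are symmetric by design; self-loops (i, i) model autocrine
signaling and multi-cell spots.  Vertex permutation of the graph (holding
expression on vertices fixed) generates the null distribution for the
significance test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "SpatialGraph",
    "build_grid_graph",
    "build_radius_graph",
    "selfloop_graph",
    "celltype_subgraph",
    "permute_graph",
    "hex_grid_coords",
]

#: relative slack on the adjacency distance cut-off, absorbs float jitter in
#: micrometre coordinates
DISTANCE_TOL = 1e-6


@dataclass
class SpatialGraph:
    """Directed spot adjacency graph with optional weights and labels.

    ``edges`` is an (m, 2) integer array of 0-based (ligand-side,
    receptor-side) vertex pairs.  ``parent_vertices`` records the old->new
    index map when the graph is a re-indexed subgraph of another graph
    (``parent_vertices[new] = old``).
    """

    n_vertices: int
    edges: np.ndarray
    coords: np.ndarray | None = None
    weights: np.ndarray | None = None
    labels: np.ndarray | None = None
    parent_vertices: np.ndarray | None = None
    _validated: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if self.edges.size and (
            self.edges.min() < 0 or self.edges.max() >= self.n_vertices
        ):
            raise ValueError("edge endpoints outside [0, n_vertices)")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape[0] != self.edges.shape[0]:
                raise ValueError("weights length must match edge count")
            if np.any(self.weights <= 0):
                raise ValueError("edge weights must be strictly positive")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        if self.labels is not None:
            self.labels = np.asarray(self.labels)

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def sources(self) -> np.ndarray:
        return self.edges[:, 0]

    @property
    def targets(self) -> np.ndarray:
        return self.edges[:, 1]

    def self_loop_count(self) -> int:
        return int((self.edges[:, 0] == self.edges[:, 1]).sum())

    def is_symmetric(self) -> bool:
        """True when (i, j) in E implies (j, i) in E."""
        fwd = {(int(i), int(j)) for i, j in self.edges}
        return all((j, i) in fwd for i, j in fwd)

    def edge_list_tsv(self, path) -> None:
        w = self.weights if self.weights is not None else np.ones(self.n_edges)
        with open(path, "w") as fh:
            fh.write("i\tj\tw\n")
            for (i, j), wij in zip(self.edges, w):
                fh.write(f"{i}\t{j}\t{wij:g}\n")


def _radius_edges(coords: np.ndarray, cutoff: float) -> np.ndarray:
    """All ordered pairs (i, j), i != j, with ||s_i - s_j|| <= cutoff."""
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if pairs.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    return np.vstack([pairs, pairs[:, ::-1]]).astype(np.int64)


def _append_self_loops(edges: np.ndarray, n: int) -> np.ndarray:
    loops = np.repeat(np.arange(n, dtype=np.int64)[:, None], 2, axis=1)
    return np.vstack([edges, loops]) if edges.size else loops


def _warn_duplicates(coords: np.ndarray) -> None:
    uniq = np.unique(coords, axis=0)
    if uniq.shape[0] < coords.shape[0]:
        warnings.warn("duplicate spot coordinates detected", stacklevel=3)


def build_grid_graph(
    coords,
    layout: str = "hex",
    spacing: float = 1.0,
    self_loops: bool = True,
    labels=None,
) -> SpatialGraph:
    """Adjacency graph for spots on a (hex or rect) grid.

    Spots at Euclidean distance <= ``spacing * (1 + tol)`` become mutual
    directed neighbors; on a hexagonal lattice with pitch = spacing this
    yields 6 neighbors for interior spots, on a rectangular lattice 4.
    """
    if layout not in ("hex", "rect"):
        raise ValueError(f"unknown layout {layout!r}")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    _warn_duplicates(coords)
    edges = _radius_edges(coords, spacing * (1.0 + DISTANCE_TOL))
    if self_loops:
        edges = _append_self_loops(edges, coords.shape[0])
    return SpatialGraph(coords.shape[0], edges, coords=coords, labels=labels)


def build_radius_graph(
    coords,
    threshold: float,
    self_loops: bool = True,
    labels=None,
) -> SpatialGraph:
    """Fixed-radius neighbor graph for irregular spot geometries."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    _warn_duplicates(coords)
    edges = _radius_edges(coords, threshold)
    if edges.size == 0 and coords.shape[0] > 1:
        warnings.warn("distance threshold yields no neighbor edges", stacklevel=2)
    if self_loops:
        edges = _append_self_loops(edges, coords.shape[0])
    return SpatialGraph(coords.shape[0], edges, coords=coords, labels=labels)


def selfloop_graph(n: int, coords=None) -> SpatialGraph:
    """Graph with only the n self-loops; one edge per sample, used for
    non-spatial fitting where each (ligand, receptor) pair is one draw."""
    edges = _append_self_loops(np.empty((0, 2), dtype=np.int64), n)
    return SpatialGraph(n, edges, coords=coords)


def hex_grid_coords(n_rows: int, n_cols: int, pitch: float = 100.0) -> np.ndarray:
    """Offset-row hexagonal lattice positions (Visium-style, pitch in µm)."""
    rows, cols = np.mgrid[0:n_rows, 0:n_cols]
    x = (cols + 0.5 * (rows % 2)) * pitch
    y = rows * (np.sqrt(3) / 2) * pitch
    return np.column_stack([x.ravel(), y.ravel()]).astype(float)


def celltype_subgraph(g: SpatialGraph, c, c2) -> SpatialGraph:
    """Restrict to interactions between cell types ``c`` and ``c2``.

    Vertices: spots labeled c or c2.  Edges: (i, j) with labels (c, c2) or
    (c2, c); for c == c2 this keeps edges with both endpoints labeled c,
    self-loops included.  Vertex indices are re-mapped to 0..k-1 with the
    original indices recorded in ``parent_vertices``.
    """
    if g.labels is None:
        raise ValueError("graph has no cell-type labels")
    lab = g.labels
    keep_vertex = (lab == c) | (lab == c2)
    if not keep_vertex.any():
        warnings.warn(f"no vertices labeled {c!r} or {c2!r}", stacklevel=2)
    old_idx = np.flatnonzero(keep_vertex)
    old_to_new = -np.ones(g.n_vertices, dtype=np.int64)
    old_to_new[old_idx] = np.arange(old_idx.size)

    src_lab = lab[g.sources]
    tgt_lab = lab[g.targets]
    keep_edge = ((src_lab == c) & (tgt_lab == c2)) | ((src_lab == c2) & (tgt_lab == c))
    edges = old_to_new[g.edges[keep_edge]]
    weights = g.weights[keep_edge] if g.weights is not None else None
    return SpatialGraph(
        old_idx.size,
        edges,
        coords=g.coords[old_idx] if g.coords is not None else None,
        weights=weights,
        labels=lab[old_idx],
        parent_vertices=old_idx,
    )


def random_vertex_permutation(
    n: int, rng: np.random.Generator, restrict_to=None
) -> np.ndarray:
    """Uniform permutation of ``restrict_to`` (default: all vertices),
    fixing every vertex outside the restriction."""
    perm = np.arange(n, dtype=np.int64)
    if restrict_to is None:
        sub = perm
    else:
        sub = np.asarray(sorted(set(int(v) for v in restrict_to)), dtype=np.int64)
        if sub.size and (sub.min() < 0 or sub.max() >= n):
            raise ValueError("restrict_to contains out-of-range vertices")
    perm[sub] = rng.permutation(sub)
    return perm


def permute_graph(
    g: SpatialGraph,
    seed: int | np.random.Generator,
    restrict_to=None,
) -> SpatialGraph:
    """Null graph G' with edges {(pi(i), pi(j))} for a uniform permutation pi.

    Expression stays attached to vertices, so relabeling the graph's
    endpoints is equivalent to shuffling which spots are adjacent.  Edge
    count, self-loop count, and the degree multiset are preserved.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = random_vertex_permutation(g.n_vertices, rng, restrict_to)
    return SpatialGraph(
        g.n_vertices,
        perm[g.edges],
        coords=g.coords,
        weights=g.weights,
        labels=g.labels,
    )
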