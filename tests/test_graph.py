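import itertools

import numpy as np
import pytest
from scipy import stats

from copulacci import (
    SpatialGraph,
    build_grid_graph,
    build_radius_graph,
    celltype_subgraph,
    hex_grid_coords,
    permute_graph,
    selfloop_graph,
)
from copulacci.graph import random_vertex_permutation


def edge_set(g):
    return {(int(i), int(j)) for i, j in g.edges}


class TestGridGraph:
    def test_single_spot_self_loop_only(self):
        g = build_grid_graph([[0.0, 0.0]], layout="rect", spacing=1.0, self_loops=True)
        assert edge_set(g) == {(0, 0)}

    def test_2x2_unit_grid_edge_count(self):
        coords = [[0, 0], [0, 1], [1, 0], [1, 1]]
        g = build_grid_graph(coords, layout="rect", spacing=1.0, self_loops=True)
        # oracle: enumerate all pairwise distances
        expected = set()
        for i, j in itertools.permutations(range(4), 2):
            d = np.hypot(*(np.array(coords[i]) - coords[j]))
            if d <= 1.0 + 1e-9:
                expected.add((i, j))
        expected |= {(i, i) for i in range(4)}
        assert edge_set(g) == expected
        assert g.n_edges == 12

    def test_hex_interior_vertex_has_6_neighbors(self):
        coords = hex_grid_coords(5, 5, pitch=100.0)
        g = build_grid_graph(coords, layout="hex", spacing=100.0, self_loops=False)
        center = 12  # row 2, col 2
        assert int((g.sources == center).sum()) == 6

    def test_spacing_must_be_positive(self):
        with pytest.raises(ValueError):
            build_grid_graph([[0, 0]], spacing=0.0)

    def test_duplicate_coordinates_warn(self):
        with pytest.warns(UserWarning, match="duplicate"):
            build_grid_graph([[0, 0], [0, 0]], layout="rect", spacing=1.0)

    def test_symmetry(self):
        coords = hex_grid_coords(4, 4)
        g = build_grid_graph(coords, layout="hex", spacing=100.0, self_loops=True)
        assert g.is_symmetric()


class TestRadiusGraph:
    def test_small_threshold_only_self_loops(self):
        coords = [[0, 0], [5, 0], [0, 5]]
        with pytest.warns(UserWarning):
            g = build_radius_graph(coords, threshold=1.0, self_loops=True)
        assert edge_set(g) == {(0, 0), (1, 1), (2, 2)}

    def test_large_threshold_complete(self):
        coords = [[0, 0], [1, 0], [0, 1]]
        g = build_radius_graph(coords, threshold=10.0, self_loops=True)
        assert edge_set(g) == {(i, j) for i in range(3) for j in range(3)}

    def test_matches_all_pairs_bruteforce(self, rng):
        coords = rng.uniform(size=(50, 2))
        g = build_radius_graph(coords, threshold=0.2, self_loops=False)
        expected = {
            (i, j)
            for i in range(50)
            for j in range(50)
            if i != j and np.hypot(*(coords[i] - coords[j])) <= 0.2
        }
        assert edge_set(g) == expected


class TestCelltypeSubgraph:
    def test_identity_restriction(self, path_graph):
        g = SpatialGraph(3, path_graph.edges, labels=np.array(["c", "c", "c"]))
        sub = celltype_subgraph(g, "c", "c")
        assert edge_set(sub) == edge_set(g)

    def test_bipartite_path_example(self, path_graph):
        sub = celltype_subgraph(path_graph, "c", "c2")
        # labels (c, c2, c): cross-label edges kept, self-loops dropped
        assert edge_set(sub) == {(0, 1), (1, 0), (1, 2), (2, 1)}
        np.testing.assert_array_equal(sub.parent_vertices, [0, 1, 2])

    def test_absent_label_gives_empty_edges(self, path_graph):
        with pytest.warns(UserWarning):
            sub = celltype_subgraph(path_graph, "zzz", "yyy")
        assert sub.n_edges == 0

    def test_label_order_symmetric(self, path_graph):
        a = celltype_subgraph(path_graph, "c", "c2")
        b = celltype_subgraph(path_graph, "c2", "c")
        assert edge_set(a) == edge_set(b)


class TestPermuteGraph:
    def test_edge_count_and_self_loops_preserved(self, path_graph, rng):
        gp = permute_graph(path_graph, rng)
        assert gp.n_edges == path_graph.n_edges
        assert gp.self_loop_count() == path_graph.self_loop_count()

    def test_degree_multiset_preserved(self, rng):
        coords = rng.uniform(size=(20, 2))
        g = build_radius_graph(coords, threshold=0.4)
        gp = permute_graph(g, 42)
        for axis in (0, 1):
            a = np.sort(np.bincount(g.edges[:, axis], minlength=20))
            b = np.sort(np.bincount(gp.edges[:, axis], minlength=20))
            np.testing.assert_array_equal(a, b)

    def test_restriction_fixes_outside_vertices(self, rng):
        perm = random_vertex_permutation(10, rng, restrict_to=[2, 3, 4])
        fixed = [i for i in range(10) if i not in (2, 3, 4)]
        assert all(perm[i] == i for i in fixed)
        assert sorted(perm[[2, 3, 4]]) == [2, 3, 4]

    def test_permutation_uniformity_4_vertices(self):
        """Sampled permutations of 4 vertices hit all 24 outcomes uniformly
        (chi-square goodness of fit on 30000 draws)."""
        rng = np.random.default_rng(7)
        counts = {}
        n_draws = 30000
        for _ in range(n_draws):
            p = tuple(random_vertex_permutation(4, rng))
            counts[p] = counts.get(p, 0) + 1
        assert len(counts) == 24
        chi2 = stats.chisquare(list(counts.values()))
        assert chi2.pvalue > 1e-3

    def test_selfloop_graph_shape(self):
        g = selfloop_graph(5)
        assert edge_set(g) == {(i, i) for i in range(5)}
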