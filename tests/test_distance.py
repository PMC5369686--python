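"""Effective-distance operations against independent oracles and circuit laws."""

import networkx as nx
import numpy as np
import pytest
import scipy.sparse as sp

from effdist import (
    CostRaster,
    FocalNodes,
    build_graph,
    commute_time,
    compute_pair_table,
    least_cost_distance,
    linearized_redundancy,
    redundancy,
    resistance_distance,
)
from effdist.graph import LatticeGraph
from effdist.landscape import place_nodes


def graph_from_edges(n, edges):
    """LatticeGraph wrapper around an arbitrary undirected edge list."""
    i, j, r = zip(*edges)
    w = sp.coo_matrix(
        (list(r) + list(r), (list(i) + list(j), list(j) + list(i))), shape=(n, n)
    ).tocsr()
    # dim is only used to translate (row, col) coords; use a 1-row layout
    return LatticeGraph(resistance=w, dim=n)


def line_nodes(a, b):
    return FocalNodes(np.array([[0, a], [0, b]]))


def random_raster(dim, rng):
    return CostRaster(rng.integers(1, 1001, size=(dim, dim)))


def dense_pinv_resistance(graph, ids):
    """Oracle: R(a,b) from the dense Moore-Penrose pseudoinverse of L."""
    L = graph.laplacian().toarray()
    # explicit cutoff isolates the single constant null direction of L
    Lp = np.linalg.pinv(L, rcond=1e-10, hermitian=True)
    out = np.zeros((len(ids), len(ids)))
    for x, a in enumerate(ids):
        for y, b in enumerate(ids):
            out[x, y] = Lp[a, a] + Lp[b, b] - 2 * Lp[a, b]
    return out


def to_networkx(graph):
    g = nx.Graph()
    coo = sp.triu(graph.resistance, k=1).tocoo()
    for i, j, r in zip(coo.row, coo.col, coo.data):
        g.add_edge(int(i), int(j), weight=float(r))
    return g


class TestLeastCost:
    def test_uniform_row_distance(self):
        rng = np.random.default_rng(0)
        r = CostRaster(np.full((8, 8), 10, dtype=np.int64))
        g = build_graph(r)
        nodes = FocalNodes(np.array([[3, 1], [3, 6]]))
        lcd = least_cost_distance(g, nodes)
        assert lcd[0, 1] == pytest.approx(50.0)  # 5 orthogonal steps x r=10

    def test_chain_series_sum(self):
        g = graph_from_edges(3, [(0, 1, 3.0), (1, 2, 5.0)])
        nodes = line_nodes(0, 2)
        assert least_cost_distance(g, nodes)[0, 1] == pytest.approx(8.0)

    def test_exhaustive_simple_path_oracle_4x4(self, rng):
        raster = random_raster(4, rng)
        g = build_graph(raster)
        nodes = FocalNodes(np.array([[0, 0], [3, 3], [0, 3]]))
        lcd = least_cost_distance(g, nodes)
        nxg = to_networkx(g)
        ids = nodes.ids(4)
        for x in range(3):
            for y in range(x + 1, 3):
                best = min(
                    sum(
                        nxg[u][v]["weight"]
                        for u, v in zip(path, path[1:])
                    )
                    for path in nx.all_simple_paths(nxg, int(ids[x]), int(ids[y]))
                )
                assert lcd[x, y] == pytest.approx(best)

    def test_all_pairs_matches_networkx_on_6x6(self, rng):
        raster = random_raster(6, rng)
        g = build_graph(raster)
        nodes = place_nodes(raster, n=6, buffer_frac=0.0, seed=1)
        lcd = least_cost_distance(g, nodes)
        nxg = to_networkx(g)
        ids = nodes.ids(6)
        for x in range(6):
            for y in range(6):
                expect = nx.dijkstra_path_length(nxg, int(ids[x]), int(ids[y]))
                assert lcd[x, y] == pytest.approx(expect)


class TestResistance:
    def test_single_resistor(self):
        g = graph_from_edges(2, [(0, 1, 7.0)])
        r = resistance_distance(g, line_nodes(0, 1))
        assert r[0, 1] == pytest.approx(7.0)

    def test_chain_equals_least_cost(self):
        g = graph_from_edges(3, [(0, 1, 3.0), (1, 2, 5.0)])
        nodes = line_nodes(0, 2)
        assert resistance_distance(g, nodes)[0, 1] == pytest.approx(8.0)

    @pytest.mark.parametrize("dim", [5, 6])
    def test_dense_pseudoinverse_oracle(self, dim, rng):
        raster = random_raster(dim, rng)
        g = build_graph(raster)
        nodes = place_nodes(raster, n=5, buffer_frac=0.0, seed=2)
        got = resistance_distance(g, nodes)
        want = dense_pinv_resistance(g, nodes.ids(dim))
        assert np.allclose(got, want, rtol=1e-8, atol=1e-10)

    def test_metric_axioms_small_graphs(self, rng):
        for trial in range(5):
            raster = random_raster(5, np.random.default_rng(trial))
            g = build_graph(raster)
            nodes = place_nodes(raster, n=5, buffer_frac=0.0, seed=trial)
            R = resistance_distance(g, nodes)
            assert np.allclose(R, R.T)
            assert np.all(R[~np.eye(5, dtype=bool)] > 0)
            for a in range(5):
                for b in range(5):
                    for c in range(5):
                        assert R[a, c] <= R[a, b] + R[b, c] + 1e-9

    def test_rayleigh_monotonicity(self, rng):
        base = random_raster(4, rng)
        nodes = FocalNodes(np.array([[0, 0], [3, 3]]))
        r0 = resistance_distance(build_graph(base), nodes)[0, 1]
        for cell in [(1, 1), (0, 3), (2, 2)]:
            v = base.values.copy()
            v[cell] = min(1000, v[cell] + 300)
            r1 = resistance_distance(build_graph(CostRaster(v)), nodes)[0, 1]
            assert r1 >= r0 - 1e-9


class TestCommuteTime:
    def test_single_edge(self):
        g = graph_from_edges(2, [(0, 1, 4.0)])  # conductance 1/4, vol = 2*(1/4)
        ct = commute_time(g, line_nodes(0, 1))
        assert ct[0, 1] == pytest.approx(2.0)

    def test_proportional_to_resistance(self, rng):
        raster = random_raster(4, rng)
        g = build_graph(raster)
        nodes = place_nodes(raster, n=6, buffer_frac=0.0, seed=3)
        R = resistance_distance(g, nodes)
        CT = commute_time(g, nodes, resistance=None)
        iu = np.triu_indices(6, 1)
        ratio = CT[iu] / R[iu]
        assert np.allclose(ratio, ratio[0], rtol=1e-10)
        assert ratio[0] == pytest.approx(g.volume())


class TestRedundancy:
    def test_chain_is_one(self):
        g = graph_from_edges(4, [(0, 1, 2.0), (1, 2, 3.0), (2, 3, 4.0)])
        nodes = line_nodes(0, 3)
        lcd = least_cost_distance(g, nodes)[0, 1]
        rhat = resistance_distance(g, nodes)[0, 1]
        assert redundancy(lcd, rhat) == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_k_parallel_identical_paths(self, k):
        # k node-disjoint 2-edge paths of total cost 10 between nodes 0, 1
        edges = []
        for p in range(k):
            mid = 2 + p
            edges += [(0, mid, 4.0), (mid, 1, 6.0)]
        g = graph_from_edges(2 + k, edges)
        nodes = line_nodes(0, 1)
        lcd = least_cost_distance(g, nodes)[0, 1]
        rhat = resistance_distance(g, nodes)[0, 1]
        assert lcd == pytest.approx(10.0)
        assert redundancy(lcd, rhat) == pytest.approx(k)

    def test_lattice_redundancy_at_least_one(self, rng):
        for trial in range(5):
            raster = random_raster(6, np.random.default_rng(100 + trial))
            table = compute_pair_table(
                raster, place_nodes(raster, n=5, buffer_frac=0.0, seed=trial)
            )
            assert (table.redundancy >= 1 - 1e-9).all()
            assert (table.least_cost >= table.resistance - 1e-9).all()

    def test_linearized_modes(self):
        assert linearized_redundancy(4.0, 2.0, "sqrt_lcd") == pytest.approx(1.0)
        assert linearized_redundancy(4.0, 2.0, "squared_r") == pytest.approx(1.0)
        with pytest.raises(ValueError):
            linearized_redundancy(4.0, 2.0, "cube")
        with pytest.raises(ValueError):
            redundancy(4.0, 0.0)
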