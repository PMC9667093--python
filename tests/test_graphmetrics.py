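"""Graph metrics against hand-worked values and independent brute-force oracles.

Oracles here are deliberately naive: Floyd-Warshall for distances, O(n^3)
triple enumeration for triangles, exhaustive geodesic enumeration for
betweenness, induced-subgraph recomputation for local efficiency.
"""

import numpy as np
import pytest

import connectoml as cm

# --- canonical small graphs ------------------------------------------------

K3 = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=np.uint8)
P3 = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.uint8)
STAR = np.zeros((4, 4), dtype=np.uint8)
STAR[0, 1:] = STAR[1:, 0] = 1  # K1,3 with center 0
K4 = (1 - np.eye(4)).astype(np.uint8)
TWO_K2 = np.zeros((4, 4), dtype=np.uint8)
TWO_K2[0, 1] = TWO_K2[1, 0] = TWO_K2[2, 3] = TWO_K2[3, 2] = 1


# --- oracles ---------------------------------------------------------------

def floyd_warshall(adj):
    n = len(adj)
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def triangle_clustering(adj):
    n = len(adj)
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        k = len(nbrs)
        if k < 2:
            continue
        t = sum(
            adj[u, v] for ai, u in enumerate(nbrs) for v in nbrs[ai + 1 :]
        )
        out[i] = 2.0 * t / (k * (k - 1))
    return out


def geodesic_betweenness(adj):
    """Count all shortest paths by exhaustive BFS path enumeration."""
    import itertools
    n = len(adj)
    d = floyd_warshall(adj)
    through = np.zeros(n)

    def count_paths(s, t, via):
        # number of geodesics s->t and how many pass through `via`
        if not np.isfinite(d[s, t]):
            return 0, 0
        total = passing = 0
        frontier = [(s, [s])]
        while frontier:
            node, path = frontier.pop()
            if node == t:
                total += 1
                passing += via in path[1:-1]
                continue
            for nxt in np.flatnonzero(adj[node]):
                if d[s, nxt] == len(path) and d[nxt, t] == d[s, t] - len(path):
                    frontier.append((nxt, path + [nxt]))
        return total, passing

    for v in range(n):
        for s, t in itertools.combinations([x for x in range(n) if x != v], 2):
            total, passing = count_paths(s, t, v)
            if total:
                through[v] += passing / total
    norm = (n - 1) * (n - 2) / 2
    return through / norm


# --- worked examples -------------------------------------------------------

class TestWorkedValues:
    def test_degree(self):
        assert cm.degree_centrality(STAR).tolist() == [3, 1, 1, 1]
        assert cm.degree_centrality(np.zeros((3, 3))).tolist() == [0, 0, 0]

    def test_clustering(self):
        assert np.allclose(cm.nodal_clustering(K3), 1.0)
        assert cm.clustering_coefficient(K3) == 1.0
        assert np.allclose(cm.nodal_clustering(STAR), 0.0)

    def test_path_lengths(self):
        d = cm.shortest_path_lengths(P3)
        assert d[0, 2] == 2
        assert cm.characteristic_path_length(d) == pytest.approx(4 / 3)
        assert cm.characteristic_path_length(cm.shortest_path_lengths(K4)) == 1.0
        # disconnected: only reachable pairs count
        d2 = cm.shortest_path_lengths(TWO_K2)
        assert np.isinf(d2[0, 2])
        assert cm.characteristic_path_length(d2) == 1.0

    def test_lp_undefined_for_edgeless_graph(self):
        with pytest.raises(ValueError, match="no edges"):
            cm.characteristic_path_length(cm.shortest_path_lengths(np.zeros((3, 3))))

    def test_efficiency(self):
        d = cm.shortest_path_lengths(P3)
        assert cm.global_efficiency(d) == pytest.approx(5 / 6)
        ne = cm.nodal_efficiency(d)
        assert ne[1] == pytest.approx(1.0)
        assert ne[0] == pytest.approx(0.75)
        assert cm.global_efficiency(cm.shortest_path_lengths(K4)) == 1.0

    def test_local_efficiency(self):
        assert np.allclose(cm.nodal_local_efficiency(K4), 1.0)
        assert cm.nodal_local_efficiency(P3)[1] == 0.0  # unconnected neighbors

    def test_betweenness(self):
        bc = cm.betweenness_centrality(P3)
        assert bc[1] == pytest.approx(1.0)
        assert bc[0] == bc[2] == 0.0
        assert np.allclose(cm.betweenness_centrality(K4), 0.0)


# --- oracle equivalence on random graphs -----------------------------------

class TestOracleEquivalence:
    def test_distances_match_floyd_warshall(self, random_graphs):
        for adj in random_graphs[:60]:
            d = cm.shortest_path_lengths(adj)
            assert np.array_equal(d, floyd_warshall(adj))

    def test_clustering_matches_triple_enumeration(self, random_graphs):
        for adj in random_graphs[:60]:
            assert np.allclose(cm.nodal_clustering(adj), triangle_clustering(adj))

    def test_betweenness_matches_geodesic_enumeration(self, random_graphs):
        for adj in random_graphs[:40]:
            assert np.allclose(
                cm.betweenness_centrality(adj), geodesic_betweenness(adj), atol=1e-9
            )

    def test_local_efficiency_matches_induced_subgraph_oracle(self, random_graphs):
        for adj in random_graphs[:40]:
            nle = cm.nodal_local_efficiency(adj)
            for i in range(len(adj)):
                nbrs = np.flatnonzero(adj[i])
                if len(nbrs) < 2:
                    assert nle[i] == 0.0
                    continue
                sub = adj[np.ix_(nbrs, nbrs)]
                expected = cm.global_efficiency(floyd_warshall(sub))
                assert nle[i] == pytest.approx(expected)

    def test_degree_matches_edge_recount(self, random_graphs):
        for adj in random_graphs[:60]:
            iu, ju = np.nonzero(np.triu(adj, 1))
            recount = np.zeros(len(adj), dtype=int)
            for u, v in zip(iu, ju):
                recount[u] += 1
                recount[v] += 1
            assert np.array_equal(cm.degree_centrality(adj), recount)

    def test_bounds_and_handshake(self, random_graphs):
        for adj in random_graphs:
            dc = cm.degree_centrality(adj)
            assert dc.sum() == adj.sum()  # sum DC = 2|E|
            assert np.all((cm.nodal_clustering(adj) >= 0) & (cm.nodal_clustering(adj) <= 1))
            d = cm.shortest_path_lengths(adj)
            assert 0 <= cm.global_efficiency(d) <= 1
            bc = cm.betweenness_centrality(adj)
            assert np.all((bc >= -1e-12) & (bc <= 1 + 1e-12))


# --- null model and small-world indices ------------------------------------

class TestRewiring:
    def test_degree_sequence_preserved_and_simple(self):
        rng = np.random.default_rng(0)
        a = (rng.random((40, 40)) < 0.15).astype(np.uint8)
        a = np.triu(a, 1)
        a = a + a.T
        r = cm.rewire_preserving_degrees(a, swaps_per_edge=10, seed=1)
        assert np.array_equal(r.sum(1), a.sum(1))
        assert np.all(np.diag(r) == 0)
        assert np.all((r == 0) | (r == 1))
        assert not np.array_equal(r, a)  # actually rewired

    def test_rigid_graph_best_effort(self):
        with pytest.warns(UserWarning, match="stalled"):
            r = cm.rewire_preserving_degrees(K4, swaps_per_edge=10, seed=0)
        assert np.array_equal(r, K4)

    def test_ring_lattice_clustering_drops(self):
        # small-world hallmark: randomization destroys lattice clustering
        n, k = 50, 4
        a = np.zeros((n, n), dtype=np.uint8)
        for i in range(n):
            for s in range(1, k // 2 + 1):
                j = (i + s) % n
                a[i, j] = a[j, i] = 1
        cp0 = cm.clustering_coefficient(a)
        drops = sum(
            cm.clustering_coefficient(cm.rewire_preserving_degrees(a, 10, seed=s)) < cp0
            for s in range(20)
        )
        assert drops >= 19


class TestSmallWorld:
    def test_self_ensemble_normalizes_to_one(self, monkeypatch):
        a = K4.copy()
        ens = cm.NullEnsemble(n_random=3, swaps_per_edge=0, seed=0)
        gamma, lam, sigma = cm.small_world_indices(a, ens)
        assert gamma == lam == sigma == 1.0

    def test_watts_strogatz_regime(self):
        import networkx as nx
        g = nx.watts_strogatz_graph(100, 6, 0.1, seed=4)
        a = nx.to_numpy_array(g, dtype=np.uint8)
        ens = cm.NullEnsemble(n_random=20, swaps_per_edge=5, seed=9)
        gamma, lam, sigma = cm.small_world_indices(a, ens)
        assert gamma > 1
        assert lam < 1.5
        assert sigma == pytest.approx(gamma / lam)

    def test_random_graph_gamma_near_one(self):
        import networkx as nx
        g = nx.gnp_random_graph(200, 0.05, seed=11)
        a = nx.to_numpy_array(g, dtype=np.uint8)
        ens = cm.NullEnsemble(n_random=10, swaps_per_edge=5, seed=12)
        gamma, _, _ = cm.small_world_indices(a, ens)
        assert abs(gamma - 1) < 0.2
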