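"""Pen-network construction and centrality traits vs brute-force oracles."""

import itertools

import numpy as np
import pytest

from pigsna.network import (
    DegenerateNetworkError,
    InteractionRecord,
    NetworkDataError,
    PenNetwork,
    betweenness_centrality,
    build_pen_network,
    categorize_betweenness,
    clique_membership,
    closeness_centrality,
    clustering_coefficient,
    compute_sna_traits,
    degree_centrality,
    eigenvector_centrality,
)


def net_from_edges(nodes, edges):
    n = len(nodes)
    pos = {v: i for i, v in enumerate(nodes)}
    adj = np.zeros((n, n), dtype=bool)
    for a, b in edges:
        adj[pos[a], pos[b]] = adj[pos[b], pos[a]] = True
    return PenNetwork(0, list(nodes), adj)


def random_net(rng, n, p=0.4):
    adj = rng.random((n, n)) < p
    adj = np.triu(adj, 1)
    adj = adj | adj.T
    return PenNetwork(0, list(range(n)), adj)


# ---------------------------------------------------------------------------
# brute-force oracles (independent of networkx)


def bf_distances(adj):
    n = len(adj)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0)
    dist[adj] = 1
    for k in range(n):  # Floyd-Warshall
        dist = np.minimum(dist, dist[:, k][:, None] + dist[k, :][None, :])
    return dist


def bf_betweenness(adj):
    """Enumerate every simple path; count geodesics through each node."""
    n = len(adj)
    dist = bf_distances(adj)
    score = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        if not np.isfinite(dist[s, t]):
            continue
        length = int(dist[s, t])
        geodesics = [
            (s, *mid, t)
            for mid in itertools.permutations(
                [v for v in range(n) if v not in (s, t)], max(length - 1, 0)
            )
            if all(adj[a, b] for a, b in itertools.pairwise((s, *mid, t)))
        ]
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for g in geodesics if v in g)
            score[v] += through / len(geodesics)
    return score / ((n - 1) * (n - 2) / 2)


def bf_closeness(adj):
    n = len(adj)
    dist = bf_distances(adj)
    out = np.zeros(n)
    for v in range(n):
        d = dist[v]
        reach = np.isfinite(d) & (np.arange(n) != v)
        r = reach.sum()
        if r > 0:
            out[v] = (r / d[reach].sum()) * (r / (n - 1))
    return out


def bf_eigenvector(adj):
    """Power iteration on the largest component, max entry scaled to 1."""
    n = len(adj)
    dist = bf_distances(adj)
    comps = []
    seen = set()
    for v in range(n):
        if v in seen:
            continue
        comp = {u for u in range(n) if np.isfinite(dist[v, u])}
        seen |= comp
        comps.append(sorted(comp))
    comp = max(comps, key=len)
    # shift by +I so the leading eigenvalue strictly dominates even on
    # bipartite components (where lambda_min = -lambda_max); the leading
    # eigenvector is unchanged
    sub = adj[np.ix_(comp, comp)].astype(float) + np.eye(len(comp))
    x = np.ones(len(comp))
    for _ in range(10_000):
        x_new = sub @ x
        x_new /= np.linalg.norm(x_new)
        if np.abs(x_new - x).max() < 1e-13:
            break
        x = x_new
    out = np.zeros(n)
    out[comp] = np.abs(x)
    return out / out.max()


def bf_clustering(adj):
    n = len(adj)
    out = np.zeros(n)
    for v in range(n):
        nb = np.flatnonzero(adj[v])
        k = len(nb)
        if k < 2:
            continue
        links = sum(adj[a, b] for a, b in itertools.combinations(nb, 2))
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def bf_max_cliques(adj):
    n = len(adj)
    best, members = 1, set(range(n))
    for size in range(n, 1, -1):
        found = set()
        for combo in itertools.combinations(range(n), size):
            if all(adj[a, b] for a, b in itertools.combinations(combo, 2)):
                found.update(combo)
        if found:
            return size, found
    return best, members


# ---------------------------------------------------------------------------


class TestBuildPenNetwork:
    def test_fight_and_bully_combine_to_one_edge(self):
        recs = [
            InteractionRecord(1, 1, 2, "fight"),
            InteractionRecord(1, 2, 1, "bully"),
        ]
        net = build_pen_network(recs, [1, 2, 3])
        assert net.adjacency.sum() == 2  # one undirected edge
        assert net.adjacency[0, 1] and net.adjacency[1, 0]

    def test_no_records_gives_edgeless_graph_with_isolates(self):
        net = build_pen_network([], list(range(15)), pen_id=3)
        assert net.n == 15 and net.adjacency.sum() == 0

    def test_triangle(self):
        recs = [InteractionRecord(1, a, b, "fight") for a, b in [(1, 2), (2, 3), (1, 3)]]
        net = build_pen_network(recs, [1, 2, 3])
        assert net.adjacency.sum() == 6

    def test_non_member_rejected(self):
        with pytest.raises(NetworkDataError):
            build_pen_network([InteractionRecord(1, 1, 99, "fight")], [1, 2])


class TestCentralityExamples:
    def test_star_degree(self):
        net = net_from_edges(range(5), [(0, i) for i in range(1, 5)])
        raw, norm = degree_centrality(net)
        assert norm[0] == 1.0 and norm[1] == 0.25
        assert raw[0] == 4

    def test_path_betweenness(self):
        net = net_from_edges([1, 2, 3], [(1, 2), (2, 3)])
        np.testing.assert_allclose(betweenness_centrality(net), [0, 1.0, 0])

    def test_complete_graph_betweenness_zero(self):
        net = net_from_edges(range(5), itertools.combinations(range(5), 2))
        assert betweenness_centrality(net).max() == 0.0

    def test_path_closeness(self):
        net = net_from_edges([1, 2, 3], [(1, 2), (2, 3)])
        np.testing.assert_allclose(closeness_centrality(net), [2 / 3, 1.0, 2 / 3])

    def test_complete_graph_closeness_one(self):
        net = net_from_edges(range(4), itertools.combinations(range(4), 2))
        np.testing.assert_allclose(closeness_centrality(net), 1.0)

    def test_isolate_closeness_zero(self):
        net = net_from_edges(range(4), [(0, 1), (1, 2)])
        assert closeness_centrality(net)[3] == 0.0

    def test_triangle_eigenvector_all_one(self):
        net = net_from_edges(range(3), [(0, 1), (1, 2), (0, 2)])
        np.testing.assert_allclose(eigenvector_centrality(net), 1.0)

    def test_star_eigenvector_closed_form(self):
        net = net_from_edges(range(5), [(0, i) for i in range(1, 5)])
        # leaves score 1/sqrt(n-1) relative to the hub
        np.testing.assert_allclose(
            eigenvector_centrality(net), [1.0, 0.5, 0.5, 0.5, 0.5], atol=1e-10
        )

    def test_edgeless_eigenvector_warns_zero(self):
        net = net_from_edges(range(4), [])
        with pytest.warns(UserWarning):
            assert eigenvector_centrality(net).sum() == 0.0

    def test_clustering_examples(self):
        tri = net_from_edges(range(3), [(0, 1), (1, 2), (0, 2)])
        np.testing.assert_allclose(clustering_coefficient(tri), 1.0)
        path = net_from_edges(range(3), [(0, 1), (1, 2)])
        assert clustering_coefficient(path)[1] == 0.0
        k4_minus = net_from_edges(
            range(4), [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)]  # missing (2,3)
        )
        np.testing.assert_allclose(
            clustering_coefficient(k4_minus), [2 / 3, 2 / 3, 1.0, 1.0]
        )

    def test_clique_membership_k4_plus_pendant(self):
        edges = list(itertools.combinations(range(4), 2)) + [(3, 4)]
        flag, size = clique_membership(net_from_edges(range(5), edges))
        assert size == 4
        np.testing.assert_array_equal(flag, [1, 1, 1, 1, 0])

    def test_clique_membership_edgeless_degenerate(self):
        with pytest.warns(UserWarning):
            flag, size = clique_membership(net_from_edges(range(4), []))
        assert size == 1 and flag.sum() == 4

    def test_two_disjoint_triangles_all_members(self):
        edges = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]
        flag, size = clique_membership(net_from_edges(range(6), edges))
        assert size == 3 and flag.sum() == 6

    def test_degenerate_sizes_rejected(self):
        one = net_from_edges([1], [])
        with pytest.raises(DegenerateNetworkError):
            degree_centrality(one)
        with pytest.raises(DegenerateNetworkError):
            betweenness_centrality(net_from_edges([1, 2], [(1, 2)]))


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_random_graphs_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        net = random_net(rng, int(rng.integers(4, 9)))
        adj = net.adjacency
        np.testing.assert_allclose(
            betweenness_centrality(net), bf_betweenness(adj), atol=1e-12
        )
        np.testing.assert_allclose(
            closeness_centrality(net), bf_closeness(adj), atol=1e-12
        )
        np.testing.assert_allclose(
            clustering_coefficient(net), bf_clustering(adj), atol=1e-12
        )
        raw, _ = degree_centrality(net)
        np.testing.assert_array_equal(raw, adj.sum(axis=1))
        if adj.any():
            np.testing.assert_allclose(
                eigenvector_centrality(net), bf_eigenvector(adj), atol=1e-8
            )

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            n = int(rng.integers(5, 9))
            net = random_net(rng, n)
            if not net.adjacency.any():
                continue
            perm = rng.permutation(n)
            permuted = PenNetwork(
                0, list(range(n)), net.adjacency[np.ix_(perm, perm)]
            )
            for fn in (betweenness_centrality, closeness_centrality,
                       clustering_coefficient, eigenvector_centrality):
                np.testing.assert_allclose(
                    fn(permuted), fn(net)[perm], atol=1e-9
                )

    def test_adding_edge_never_decreases_degree(self):
        rng = np.random.default_rng(2)
        net = random_net(rng, 8)
        raw, _ = degree_centrality(net)
        adj = net.adjacency.copy()
        free = np.argwhere(~adj & ~np.eye(8, dtype=bool))
        i, j = free[0]
        adj[i, j] = adj[j, i] = True
        raw2, _ = degree_centrality(PenNetwork(0, list(range(8)), adj))
        assert np.all(raw2 >= raw)


class TestCategoricalBetweenness:
    def test_sixteen_distinct_values_give_four_high(self):
        high = categorize_betweenness(np.arange(16, dtype=float))
        assert high.sum() == 4
        assert np.array_equal(np.flatnonzero(high), [12, 13, 14, 15])

    def test_all_equal_is_degenerate_all_high(self):
        with pytest.warns(UserWarning):
            high = categorize_betweenness(np.ones(10))
        assert high.sum() == 10

    def test_high_group_mean_exceeds_low(self):
        rng = np.random.default_rng(1)
        v = rng.exponential(size=1000)
        high = categorize_betweenness(v)
        assert v[high == 1].mean() > v[high == 0].mean()

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            categorize_betweenness(np.array([1.0, 2.0]))


def test_compute_sna_traits_schema():
    rng = np.random.default_rng(0)
    nets = [random_net(rng, 15) for _ in range(4)]
    for k, net in enumerate(nets):
        net.pen_id = k
    table = compute_sna_traits(nets)
    assert len(table) == 60
    for col in ("sna_degree", "sna_betweenness", "sna_closeness",
                "sna_eigenvector", "sna_clustering"):
        assert table[col].between(0, 1).all()
    assert set(table["sna_clique_member"].unique()) <= {0, 1}
    assert set(table["sna_betweenness_cat"].unique()) <= {0, 1}
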