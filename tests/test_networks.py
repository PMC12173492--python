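"""COI matrices, community detection, nulls, small-world, decay fits."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mousebarn import networks, rfid
from tests.conftest import make_stays, random_stay_log


def _coi_from_rows(rows, window=None):
    stays = make_stays(rows)
    meetings = rfid.detect_meetings(stays)
    if window is None:
        window = (stays["entry"].min(), stays["exit"].max() + 1)
    return networks.compute_coi(meetings, stays, window)


class TestCoi:
    def test_declared_formula(self):
        # T_i = T_j = 100 s with 50 s overlap: 50 / (100+100-50) = 1/3
        coi = _coi_from_rows([("A", "f", "b", 0, 100),
                              ("B", "m", "b", 50, 150)])
        assert coi.value("A", "B") == pytest.approx(50 / 150)

    def test_identical_stay_sets_give_one(self):
        coi = _coi_from_rows([("A", "f", "b", 0, 100),
                              ("B", "m", "b", 0, 100),
                              ("A", "f", "b2", 200, 260),
                              ("B", "m", "b2", 200, 260)])
        assert coi.value("A", "B") == pytest.approx(1.0)

    def test_disjoint_stays_give_zero(self):
        coi = _coi_from_rows([("A", "f", "b", 0, 100),
                              ("B", "m", "b", 100, 200)])
        assert coi.value("A", "B") == 0.0

    def test_symmetric_and_bounded(self, rng):
        stays = random_stay_log(rng, n_mice=8, n_stays=150)
        meetings = rfid.detect_meetings(stays)
        coi = networks.compute_coi(meetings, stays,
                                   (0, stays["exit"].max() + 1))
        assert ((coi.pairs["coi"] > 0) & (coi.pairs["coi"] <= 1)).all()
        for _, r in coi.pairs.iterrows():
            assert coi.value(r["mouse_b"], r["mouse_a"]) \
                == pytest.approx(r["coi"])

    def test_window_restriction(self):
        # overlap of 50 s lies entirely after the window: COI must be 0
        coi = _coi_from_rows([("A", "f", "b", 0, 100),
                              ("B", "m", "b", 50, 150)], window=(0, 50))
        assert len(coi.pairs) == 0


class TestBuildNetwork:
    def test_counts(self):
        coi = _coi_from_rows([("A", "f", "b", 0, 100),
                              ("B", "m", "b", 50, 150),
                              ("C", "f", "b2", 0, 100)])
        g = networks.build_network(coi)
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 1
        assert g["A"]["B"]["weight"] == pytest.approx(1 / 3)

    def test_empty_coi_gives_edgeless_graph(self):
        coi = _coi_from_rows([("A", "f", "b", 0, 100),
                              ("B", "m", "b2", 0, 100)])
        g = networks.build_network(coi)
        assert g.number_of_edges() == 0 and g.number_of_nodes() == 2

    def test_counts_equal_matrix_recount(self, rng):
        stays = random_stay_log(rng, n_mice=10, n_stays=200)
        meetings = rfid.detect_meetings(stays)
        coi = networks.compute_coi(meetings, stays,
                                   (0, stays["exit"].max() + 1))
        g = networks.build_network(coi)
        assert g.number_of_edges() == int((coi.pairs["coi"] > 0).sum())
        assert g.number_of_nodes() == len(coi.box_time)


def _weighted(edges):
    g = nx.Graph()
    g.add_weighted_edges_from(edges)
    return g


class TestCommunities:
    def test_two_disconnected_triangles(self):
        g = _weighted([(0, 1, 1), (1, 2, 1), (0, 2, 1),
                       (3, 4, 1), (4, 5, 1), (3, 5, 1)])
        part, q = networks.detect_communities(g, seed=0)
        assert len(set(part.values())) == 2
        assert part[0] == part[1] == part[2]
        assert part[3] == part[4] == part[5]
        assert q == pytest.approx(0.5)

    def test_louvain_matches_exhaustive_on_toy_graphs(self, rng):
        """Louvain modularity never exceeds the exhaustive-search optimum
        and attains it on small weighted graphs."""
        for i in range(5):
            g = nx.gnp_random_graph(6, 0.5, seed=int(rng.integers(2**31)))
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(0.1, 1.0))
            if g.number_of_edges() < 2:
                continue
            _, q_louvain = networks.detect_communities(g, seed=i)
            _, q_best = networks.best_partition_exhaustive(g)
            assert q_louvain <= q_best + 1e-9

    def test_deterministic_given_seed(self, rng):
        g = nx.gnp_random_graph(30, 0.2, seed=4)
        for u, v in g.edges:
            g[u][v]["weight"] = 1.0
        p1, q1 = networks.detect_communities(g, seed=11)
        p2, q2 = networks.detect_communities(g, seed=11)
        assert p1 == p2 and q1 == q2

    def test_planted_partition_recovery(self):
        """Strong planted 4-block structure (n=60) is recovered with
        NMI >= 0.9."""
        from sklearn.metrics import normalized_mutual_info_score
        g = nx.planted_partition_graph(4, 15, 0.6, 0.02, seed=0)
        for u, v in g.edges:
            g[u][v]["weight"] = 1.0
        part, _ = networks.detect_communities(g, seed=0)
        truth = [u // 15 for u in sorted(g.nodes)]
        found = [part[u] for u in sorted(g.nodes)]
        assert normalized_mutual_info_score(truth, found) >= 0.9


class TestRandomize:
    def _graph(self, rng):
        g = nx.gnm_random_graph(12, 24, seed=3)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.01, 1.0))
        return g

    def test_degree_sequence_and_weights_preserved(self, rng):
        g = self._graph(rng)
        degs = sorted(dict(g.degree).values())
        weights = sorted(d["weight"] for _, _, d in g.edges(data=True))
        for h in networks.randomize_network(g, 5, seed=1):
            assert sorted(dict(h.degree).values()) == degs
            hw = sorted(d["weight"] for _, _, d in h.edges(data=True))
            assert np.allclose(hw, weights)
            assert not any(u == v for u, v in h.edges)

    def test_requires_two_edges(self):
        g = _weighted([(0, 1, 1.0)])
        with pytest.raises(ValueError):
            networks.randomize_network(g, 2)


class TestModularityTest:
    def test_edgeless_graph_errors(self):
        g = nx.Graph()
        g.add_nodes_from([1, 2, 3])
        with pytest.raises(ValueError):
            networks.modularity_test(g)

    def test_two_cliques_strongly_modular(self):
        g = nx.disjoint_union(nx.complete_graph(8), nx.complete_graph(8))
        for u, v in g.edges:
            g[u][v]["weight"] = 1.0
        res = networks.modularity_test(g, n_rand=30, seed=0)
        assert res.z > 5
        assert res.q_actual > res.null_q.max()

    def test_null_modularities_are_valid(self):
        g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
        for u, v in g.edges:
            g[u][v]["weight"] = 1.0
        res = networks.modularity_test(g, n_rand=20, seed=1)
        assert np.all(np.abs(res.null_q) <= 1.0)


class TestSmallWorld:
    def test_watts_strogatz_sigma_above_one(self):
        g = nx.watts_strogatz_graph(100, 6, 0.1, seed=0)
        res = networks.small_world(g, n_random=10, seed=0)
        assert res.sigma > 1.0

    def test_sigma_identity_holds(self):
        g = nx.watts_strogatz_graph(60, 6, 0.2, seed=1)
        res = networks.small_world(g, n_random=5, seed=1)
        assert res.sigma == pytest.approx(
            (res.C / res.C_rand) / (res.L / res.L_rand), abs=1e-12)

    def test_path_graph_zero_clustering_yields_zero(self):
        res = networks.small_world(nx.path_graph(4), n_random=5, seed=0)
        assert res.sigma == 0.0 and res.C == 0.0

    def test_small_component_errors(self):
        with pytest.raises(ValueError):
            networks.small_world(nx.path_graph(3))


class TestNodeMetrics:
    def test_star_centre_centrality_one(self):
        g = nx.star_graph(4)
        part = {n: 0 for n in g.nodes}
        df = networks.node_metrics(g, part).set_index("mouse_id")
        assert df.loc[0, "degree_centrality"] == pytest.approx(1.0)

    def test_pct_communities_contacted(self):
        # node 0's neighbours span communities {0, 1} of 4 total -> 50%
        g = nx.Graph([(0, 1), (0, 2), (3, 4), (5, 6), (7, 8)])
        part = {0: 0, 1: 0, 2: 1, 3: 2, 4: 2, 5: 3, 6: 3, 7: 1, 8: 1}
        df = networks.node_metrics(g, part).set_index("mouse_id")
        assert df.loc[0, "pct_communities_contacted"] == pytest.approx(50.0)

    def test_matches_naive_recount(self, rng):
        g = nx.gnp_random_graph(20, 0.25, seed=9)
        part, _ = networks.detect_communities(
            nx.Graph([(u, v, {"weight": 1.0}) for u, v in g.edges]) if
            g.number_of_edges() else g, seed=0)
        part = {n: part.get(n, 0) for n in g.nodes}
        df = networks.node_metrics(g, part).set_index("mouse_id")
        n_comm = len(set(part.values()))
        for node in g.nodes:
            assert df.loc[node, "degree_centrality"] == pytest.approx(
                g.degree(node) / (len(g) - 1))
            contacted = {part[nb] for nb in g.neighbors(node)}
            assert df.loc[node, "pct_communities_contacted"] \
                == pytest.approx(100 * len(contacted) / n_comm)


class TestCommunityStats:
    def test_size_percentage(self):
        part = {f"m{i}": 0 for i in range(5)}
        stays = make_stays([(f"m{i}", "f", "b1", 0, 10) for i in range(5)])
        df = networks.community_stats(part, stays, (0, 100),
                                      population_size=50, n_boxes=10)
        assert df.iloc[0]["size_pct"] == pytest.approx(10.0)

    def test_box_union(self):
        part = {"m1": 0, "m2": 0}
        stays = make_stays([("m1", "f", "1", 0, 10), ("m1", "f", "2", 20, 30),
                            ("m2", "m", "2", 0, 10), ("m2", "m", "3", 20, 30)])
        df = networks.community_stats(part, stays, (0, 100),
                                      population_size=2, n_boxes=10)
        assert df.iloc[0]["boxes_pct"] == pytest.approx(30.0)


class TestBoxSharing:
    def _layout(self):
        return pd.DataFrame({"box_id": ["1", "2", "3"],
                             "x": [0.0, 3.0, 0.0], "y": [0.0, 0.0, 4.0]})

    def test_identical_and_disjoint_user_sets(self):
        stays = make_stays([("A", "f", "1", 0, 10), ("A", "f", "2", 20, 30),
                            ("B", "m", "1", 0, 10), ("B", "m", "2", 20, 30),
                            ("C", "f", "3", 0, 10)])
        pts = networks.box_sharing_vs_distance(stays, self._layout(),
                                               (0, 100))
        pts = pts.set_index(["box_a", "box_b"])
        assert pts.loc[("1", "2"), "pct_shared"] == pytest.approx(100.0)
        assert pts.loc[("1", "3"), "pct_shared"] == pytest.approx(0.0)
        assert pts.loc[("1", "2"), "distance"] == pytest.approx(3.0)
        assert pts.loc[("2", "3"), "distance"] == pytest.approx(5.0)

    def test_hand_built_set_arithmetic(self):
        # users(1) = {A,B}, users(2) = {B,C}: share 1 of 3 -> 33.3%
        stays = make_stays([("A", "f", "1", 0, 10), ("B", "m", "1", 0, 10),
                            ("B", "m", "2", 20, 30), ("C", "f", "2", 0, 10)])
        pts = networks.box_sharing_vs_distance(stays, self._layout(),
                                               (0, 100))
        pts = pts.set_index(["box_a", "box_b"])
        assert pts.loc[("1", "2"), "pct_shared"] == pytest.approx(100 / 3)

    def test_unoccupied_pairs_omitted(self):
        stays = make_stays([("A", "f", "1", 0, 10)])
        pts = networks.box_sharing_vs_distance(stays, self._layout(),
                                               (0, 100))
        # pair (2,3) has no inhabitants at all and is dropped
        assert set(map(tuple, pts[["box_a", "box_b"]].values)) \
            == {("1", "2"), ("1", "3")}


class TestFitDecay:
    def test_exact_recovery_on_noiseless_data(self):
        x = np.arange(6, dtype=float)
        y = 2.0 * np.exp(-0.5 * x)
        fit = networks.fit_decay(np.column_stack([x, y]))
        assert fit.a == pytest.approx(2.0, abs=1e-6)
        assert fit.b == pytest.approx(0.5, abs=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_constant_data_degenerate_limit(self):
        x = np.arange(5, dtype=float)
        y = np.full(5, 3.0)
        fit = networks.fit_decay(np.column_stack([x, y]))
        assert fit.b == pytest.approx(0.0, abs=1e-6)
        assert fit.a == pytest.approx(3.0, rel=1e-3)

    def test_noisy_recovery(self, rng):
        x = np.linspace(0, 8, 40)
        hits = 0
        for _ in range(20):
            y = 2.0 * np.exp(-0.5 * x) * (1 + 0.1 * rng.standard_normal(40))
            fit = networks.fit_decay(np.column_stack([x, y]))
            if abs(fit.a - 2.0) / 2.0 < 0.1 and abs(fit.b - 0.5) / 0.5 < 0.1:
                hits += 1
        assert hits >= 16

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            networks.fit_decay(np.array([[0, 1.0], [1, 0.5]]))
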