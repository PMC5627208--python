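"""Decayed daily graphs, clique percolation, turnover and distance coupling."""

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from kinclique.community import (band_distance, community_distance_model,
                                 cpm_communities, edge_weight_series,
                                 edge_weights, haversine_m, leave_probability,
                                 track_communities)
from kinclique.matrices import labelled_matrix


def pair_events(rows):
    return pd.DataFrame(rows, columns=["day", "id_a", "id_b"])


class TestEdgeWeights:
    def test_exponential_decay_closed_form(self):
        ev = pair_events([(1, "a", "b")])
        hl = 4.0
        w1 = edge_weights(ev, day=1, half_life_days=hl)
        w5 = edge_weights(ev, day=5, half_life_days=hl)
        assert w1.at["a", "b"] == pytest.approx(1.0)
        assert w5.at["a", "b"] == pytest.approx(0.5)   # one half-life later
        w3 = edge_weights(ev, day=3, half_life_days=hl)
        assert w3.at["a", "b"] == pytest.approx(2 ** (-2 / 4))

    def test_infinite_half_life_is_cumulative_count(self):
        ev = pair_events([(1, "a", "b"), (2, "a", "b"), (5, "a", "b")])
        w = edge_weights(ev, day=10, half_life_days=float("inf"))
        assert w.at["a", "b"] == pytest.approx(3.0)

    def test_day_before_first_event_empty(self):
        ev = pair_events([(5, "a", "b")])
        w = edge_weights(ev, day=1, half_life_days=7)
        assert w.to_numpy().sum() == 0.0

    def test_invalid_half_life(self):
        with pytest.raises(ValueError):
            edge_weights(pair_events([(1, "a", "b")]), 1, half_life_days=0)


# --- brute-force clique-percolation oracle ---------------------------------

def brute_force_cpm(g: nx.Graph, k: int) -> set[frozenset]:
    cliques = [frozenset(c) for c in combinations(g.nodes, k)
               if all(g.has_edge(u, v) for u, v in combinations(c, 2))]
    adj = nx.Graph()
    adj.add_nodes_from(range(len(cliques)))
    for i in range(len(cliques)):
        for j in range(i + 1, len(cliques)):
            if len(cliques[i] & cliques[j]) == k - 1:
                adj.add_edge(i, j)
    comms = set()
    for comp in nx.connected_components(adj):
        comms.add(frozenset().union(*(cliques[i] for i in comp)))
    return comms


def weights_from_graph(g: nx.Graph, ids) -> pd.DataFrame:
    a = np.zeros((len(ids), len(ids)))
    idx = {v: i for i, v in enumerate(ids)}
    for u, v in g.edges:
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1.0
    return labelled_matrix(a, ids)


class TestCpm:
    def test_adjacent_triangles_merge(self):
        g = nx.Graph([(1, 2), (2, 3), (1, 3), (2, 4), (3, 4)])
        ids = ["1", "2", "3", "4"]
        g = nx.relabel_nodes(g, str)
        comms = cpm_communities(weights_from_graph(g, ids), k=3, w_star=0.5)
        assert comms == [frozenset({"1", "2", "3", "4"})]

    def test_node_shared_triangles_stay_separate(self):
        g = nx.Graph([(1, 2), (2, 3), (1, 3), (3, 4), (4, 5), (3, 5)])
        g = nx.relabel_nodes(g, str)
        ids = [str(i) for i in range(1, 6)]
        comms = cpm_communities(weights_from_graph(g, ids), k=3, w_star=0.5)
        assert set(comms) == {frozenset({"1", "2", "3"}),
                              frozenset({"3", "4", "5"})}

    def test_edgeless_graph_no_communities(self):
        w = labelled_matrix(np.zeros((4, 4)), list("abcd"))
        assert cpm_communities(w, k=3) == []

    def test_k_below_three_rejected(self):
        w = labelled_matrix(np.ones((4, 4)), list("abcd"))
        with pytest.raises(ValueError):
            cpm_communities(w, k=2)

    @pytest.mark.parametrize("k", [3, 4])
    def test_matches_brute_force_on_random_graphs(self, k):
        rng = np.random.default_rng(k)
        for rep in range(30):
            n = int(rng.integers(4, 9))
            p = rng.uniform(0.3, 0.8)
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, str)
            ids = sorted(g.nodes)
            comms = set(cpm_communities(weights_from_graph(g, ids), k=k,
                                        w_star=0.5))
            assert comms == brute_force_cpm(g, k), (k, rep)

    def test_raising_w_star_never_grows_communities(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(0, 2, size=(8, 8))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        ids = [f"n{i}" for i in range(8)]
        w = labelled_matrix(a, ids)
        lo = cpm_communities(w, k=3, w_star=0.5)
        hi = cpm_communities(w, k=3, w_star=1.2)
        for ch in hi:
            assert any(ch <= cl for cl in lo)
        assert sum(map(len, hi)) <= sum(map(len, lo))


class TestTracking:
    def test_identical_days_all_existing(self):
        daily = {1: [frozenset("abc")], 2: [frozenset("abc")]}
        tl = track_communities(daily)
        assert tl.flags[2]["EB"] == set("abc")
        assert not tl.flags[2]["NFB"]
        assert not tl.flags[1]["LND"]

    def test_join_and_leave_flags(self):
        daily = {1: [frozenset({"1", "2", "3"})],
                 2: [frozenset({"1", "2", "4"})]}
        tl = track_communities(daily)
        assert tl.flags[2]["EB"] == {"1", "2"}
        assert tl.flags[2]["NFB"] == {"4"}
        assert tl.flags[1]["LND"] == {"3"}

    def test_community_dissolves_all_leave(self):
        daily = {1: [frozenset("abc")], 2: []}
        tl = track_communities(daily)
        assert tl.flags[1]["LND"] == set("abc")
        assert tl.sizes[2] == 0

    def test_size_series(self):
        daily = {1: [frozenset("abc"), frozenset("de")],
                 2: [frozenset("abcd")]}
        # a 2-member set is not a valid 3-clique community, but tracking
        # is agnostic: sizes report the largest community per day
        tl = track_communities(daily)
        assert tl.sizes.tolist() == [3, 4]


class TestBandDistance:
    def gps(self, rows):
        return pd.DataFrame(rows, columns=["day", "lon", "lat"])

    def test_identical_centroids_zero(self):
        a = self.gps([(1, 107.9, 33.8), (1, 107.9, 33.8)])
        assert band_distance(a, a.copy())[1] == pytest.approx(0.0)

    def test_hundredth_degree_latitude_offset(self):
        a = self.gps([(1, 0.0, 0.0)])
        b = self.gps([(1, 0.0, 0.01)])
        d = band_distance(a, b)[1]
        assert d == pytest.approx(1111.9, abs=0.5)

    def test_ninety_day_series(self):
        from kinclique.synthetic import simulate_gps
        amb, bb = simulate_gps(n_days=90, seed=0)
        d = band_distance(amb, bb)
        assert len(d) == 90
        assert (d >= 0).all()


class TestDistanceModel:
    def test_constant_size_zero_correlation(self):
        sizes = pd.Series(5.0, index=range(1, 21))
        dist = pd.Series(np.linspace(100, 1200, 20), index=range(1, 21))
        m = community_distance_model(sizes, dist)
        assert m.pearson_r == 0.0 and m.spearman_r == 0.0

    def test_inverted_u_bin_ordering(self):
        """Cohesion peaks at mid distance and collapses close in."""
        rng = np.random.default_rng(2)
        days = range(1, 121)
        dist = pd.Series(rng.uniform(50, 1500, size=120), index=days)

        def size_for(d):
            if d < 200:
                return 2 + rng.integers(0, 2)
            if d < 300:
                return 5 + rng.integers(0, 3)
            if d < 900:
                return 9 + rng.integers(0, 4)
            return 4 + rng.integers(0, 3)

        sizes = pd.Series({d: size_for(x) for d, x in dist.items()})
        m = community_distance_model(sizes, dist)
        bm = m.bin_means
        assert bm["300-900"] > bm[">900"]
        assert bm["300-900"] > bm["<200"]

    def test_too_few_days_refused(self):
        sizes = pd.Series(range(5), index=range(5))
        with pytest.raises(ValueError, match="10"):
            community_distance_model(sizes, sizes)

    def test_shuffled_distances_uncorrelated(self):
        rng = np.random.default_rng(7)
        rs = []
        base_dist = pd.Series(np.linspace(100, 1200, 60), index=range(60))
        sizes = pd.Series(np.clip(12 - 0.008 * base_dist + rng.normal(0, 1, 60),
                                  2, None), index=range(60))
        for _ in range(20):
            shuffled = pd.Series(rng.permutation(base_dist.to_numpy()),
                                 index=base_dist.index)
            rs.append(community_distance_model(sizes, shuffled).pearson_r)
        assert abs(np.mean(rs)) < 0.15


class TestLeaveProbability:
    def toy_timeline(self):
        daily = {
            1: [frozenset({"a", "b", "c", "d", "e"})],
            2: [frozenset({"a", "b", "c"})],
            3: [frozenset({"a", "b"})],
            4: [frozenset({"a", "b"})],
        }
        return track_communities(daily)

    def test_hand_counted_probabilities(self):
        tl = self.toy_timeline()
        rows = []
        for d in (1, 2, 3):
            for ind in tl.members(d):
                # high contact for the individuals that leave
                left = ind in tl.flags[d]["LND"]
                rows.append({"day": d, "id": ind,
                             "rate": 5.0 if left else 0.5})
        contact = pd.DataFrame(rows)
        out = leave_probability(tl, contact, bins=(1.0,))
        # low-contact bin: 7 stay-person-days, 0 leaves
        assert out.loc["<=1", "p_leave"] == pytest.approx(0.0)
        # high-contact bin: 3 person-days (d,e day1; c day2), all leave
        assert out.loc[">1", "person_days"] == 3
        assert out.loc[">1", "p_leave"] == pytest.approx(1.0)

    def test_no_leavers_all_zero(self):
        daily = {1: [frozenset("ab")], 2: [frozenset("ab")]}
        tl = track_communities(daily)
        contact = pd.DataFrame([{"day": 1, "id": i, "rate": 1.0}
                                for i in "ab"])
        out = leave_probability(tl, contact, bins=(2.0,))
        assert out["leaves"].sum() == 0
        assert out.loc["<=2", "p_leave"] == 0.0
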