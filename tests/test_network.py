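import math

import networkx as nx
import numpy as np
import pytest

import medloc as m
from medloc.errors import ConfigurationError, InputError
from medloc.network import TransportGraph, great_circle_km


def seg(sid, a, b, category="secondary", length_km=None):
    return m.TransportSegment(id=sid, polyline=(a, b), category=category,
                              length_km=length_km)


class TestSegmentTravelTime:
    @pytest.mark.parametrize(
        "length, category, expected",
        [
            (300.0, "high_speed_railway", 1.0),
            (80.0, "secondary", 1.0),
            (0.0, "highway", 0.0),
            (60.0, "primary", 0.6),
            (120.0, "railway", 1.0),
        ],
    )
    def test_table_speeds(self, length, category, expected):
        assert m.segment_travel_time(length, category) == pytest.approx(expected)

    def test_unknown_category_rejected(self):
        with pytest.raises(ConfigurationError):
            m.segment_travel_time(10.0, "canal")

    def test_nonpositive_speed_rejected(self):
        with pytest.raises(ConfigurationError):
            m.segment_travel_time(10.0, "secondary", {"secondary": 0.0})


class TestBuildGraph:
    def test_shared_endpoint_merges_into_one_node(self):
        g = m.build_graph([seg("a", (0, 0), (1, 0)), seg("b", (1, 0), (2, 0))])
        assert g.n_nodes == 3
        assert g.n_edges == 2
        assert sorted(g.coords) == [1, 2, 3]  # consecutive ids from 1

    def test_station_links_road_and_rail(self):
        segments = [
            seg("road", (0.0, 0.0), (2.0, 0.0), "secondary"),
            seg("rail", (0.0, 1.0), (2.0, 1.0), "railway"),
        ]
        station = m.Station(id="st", lon=1.0, lat=0.5)
        g = m.build_graph(segments, [station])
        # 4 original endpoints + 1 station + 2 projection nodes
        assert g.n_nodes == 7
        link_edges = [
            (u, v) for u, v, d in g.graph.edges(data=True) if d["category"] == "link"
        ]
        assert len(link_edges) == 2
        station_nodes = set(link_edges[0]) & set(link_edges[1])
        assert len(station_nodes) == 1  # both links share the station node
        station_node = station_nodes.pop()
        assert g.graph.degree(station_node) == 2
        # rail is reachable from the road only through the station
        assert nx.is_connected(g.graph)

    def test_rail_and_road_do_not_merge_without_station(self):
        g = m.build_graph(
            [
                seg("road", (0.0, 0.0), (1.0, 0.0), "secondary"),
                seg("rail", (0.0, 0.0), (1.0, 0.0), "railway"),
            ]
        )
        # identical coordinates, but the subnetworks stay separate
        assert g.n_nodes == 4
        assert not nx.is_connected(g.graph)

    def test_deterministic_rebuild(self):
        segments = [
            seg("a", (0, 0), (1, 1)),
            seg("b", (1, 1), (2, 0), "highway"),
            seg("r", (0, 2), (2, 2), "railway"),
        ]
        stations = [m.Station(id="s1", lon=1.0, lat=1.5)]
        g1 = m.build_graph(segments, stations)
        g2 = m.build_graph(segments, stations)
        assert g1.coords == g2.coords
        e1 = sorted((u, v, d["time"]) for u, v, d in g1.graph.edges(data=True))
        e2 = sorted((u, v, d["time"]) for u, v, d in g2.graph.edges(data=True))
        assert e1 == e2

    def test_empty_segments_rejected(self):
        with pytest.raises(InputError):
            m.build_graph([])

    def test_station_without_rail_names_station(self):
        with pytest.raises(InputError, match="'lonely'"):
            m.build_graph(
                [seg("road", (0, 0), (1, 0))], [m.Station(id="lonely", lon=0, lat=0)]
            )

    def test_transfer_penalty_applied_to_link_edges(self):
        segments = [
            seg("road", (0.0, 0.0), (2.0, 0.0), "secondary"),
            seg("rail", (0.0, 1.0), (2.0, 1.0), "railway"),
        ]
        g = m.build_graph(segments, [m.Station(id="st", lon=1.0, lat=0.5)],
                          transfer_penalty_hours=0.25)
        link_times = [d["time"] for _, _, d in g.graph.edges(data=True)
                      if d["category"] == "link"]
        assert link_times == [0.25, 0.25]


class TestSnapToNetwork:
    def test_exact_node_and_tiebreak(self):
        g = m.build_graph([seg("a", (0, 0), (2, 0))])
        node_at_origin = min(
            g.coords, key=lambda n: (g.coords[n][0] - 0) ** 2 + g.coords[n][1] ** 2
        )
        assert m.snap_to_network(g, (0.0, 0.0)) == node_at_origin
        # midpoint is equidistant from both endpoints: smallest id wins
        assert m.snap_to_network(g, (1.0, 0.0)) == 1

    def test_brute_force_nearest(self):
        rng = np.random.default_rng(4)
        pts = rng.random((10, 2)) * 3
        segments = [seg(f"s{i}", tuple(pts[i]), tuple(pts[i + 1]))
                    for i in range(9)]
        g = m.build_graph(segments)
        query = (1.3, 0.7)
        ids, xy = g.node_array()
        expected = int(ids[np.argmin(np.sum((xy - query) ** 2, axis=1))])
        assert m.snap_to_network(g, query) == expected

    def test_empty_graph_rejected(self):
        empty = TransportGraph(graph=nx.MultiGraph(), coords={})
        with pytest.raises(InputError):
            m.snap_to_network(empty, (0, 0))


class TestShortestTimeMatrix:
    def _line_graph(self):
        # A-B 1 h (80 km secondary), B-C 2 h (160 km secondary); explicit lengths
        return m.build_graph(
            [
                seg("ab", (0, 0), (1, 0), length_km=80.0),
                seg("bc", (1, 0), (2, 0), length_km=160.0),
            ]
        )

    def test_single_path_and_identity(self):
        g = self._line_graph()
        a = m.snap_to_network(g, (0, 0))
        c = m.snap_to_network(g, (2, 0))
        mat = m.shortest_time_matrix(g, [a, c], [a, c])
        assert mat.time(a, c) == pytest.approx(3.0)
        assert mat.time(a, a) == 0.0

    def test_matches_floyd_warshall_oracle(self):
        rng = np.random.default_rng(7)
        n = 20
        pts = rng.random((n, 2)) * 2
        segments = [
            seg(f"p{i}", tuple(pts[i]), tuple(pts[i + 1]),
                length_km=float(rng.uniform(10, 100)))
            for i in range(n - 1)
        ]
        extra = [(int(a), int(b)) for a, b in rng.integers(0, n, size=(15, 2))
                 if a != b]
        segments += [
            seg(f"e{k}", tuple(pts[a]), tuple(pts[b]),
                length_km=float(rng.uniform(10, 100)))
            for k, (a, b) in enumerate(extra)
        ]
        g = m.build_graph(segments)
        nodes = sorted(g.coords)
        mat = m.shortest_time_matrix(g, nodes, nodes)

        # independent Floyd-Warshall on the same edge list
        idx = {v: i for i, v in enumerate(nodes)}
        nn = len(nodes)
        dist = np.full((nn, nn), np.inf)
        np.fill_diagonal(dist, 0.0)
        for u, v, d in g.graph.edges(data=True):
            iu, iv = idx[u], idx[v]
            dist[iu, iv] = min(dist[iu, iv], d["time"])
            dist[iv, iu] = dist[iu, iv]
        for k in range(nn):
            dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
        assert np.allclose(mat.times, dist, atol=1e-9)

    def test_unreachable_pair_reports_components(self):
        g = m.build_graph([seg("a", (0, 0), (1, 0)), seg("b", (5, 5), (6, 5))])
        nodes = sorted(g.coords)
        with pytest.raises(InputError, match="connected components"):
            m.shortest_time_matrix(g, nodes[:1], nodes[-1:])

    def test_symmetry_and_triangle_inequality(self):
        g = self._line_graph()
        nodes = sorted(g.coords)
        mat = m.shortest_time_matrix(g, nodes, nodes).times
        assert np.allclose(mat, mat.T)
        for i in range(len(nodes)):
            for j in range(len(nodes)):
                for k in range(len(nodes)):
                    assert mat[i, k] <= mat[i, j] + mat[j, k] + 1e-9

    def test_homogeneous_speed_reduction(self):
        # with one category everywhere, time = length / speed exactly
        g = m.build_graph(
            [seg("ab", (0, 0), (1, 0), length_km=40.0),
             seg("bc", (1, 0), (1, 1), length_km=120.0)]
        )
        nodes = sorted(g.coords)
        mat = m.shortest_time_matrix(g, nodes, nodes).times
        lengths = {}
        for u, v, d in g.graph.edges(data=True):
            lengths[(u, v)] = d["length_km"]
        a = m.snap_to_network(g, (0, 0))
        c = m.snap_to_network(g, (1, 1))
        assert mat[nodes.index(a), nodes.index(c)] == pytest.approx(160.0 / 80.0)


def test_great_circle_matches_known_distance():
    # one degree of latitude is ~111.2 km
    assert great_circle_km(0, 0, 0, 1) == pytest.approx(111.2, rel=0.01)
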