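"""The CTD scorer: diffusion, adaptive walks, encoding lengths, p-values."""

import itertools
import math

import numpy as np
import pytest

from ctdnet import (CoPerturbationNetwork, adaptive_walk, ctd_pvalue, diffuse,
                    information_content)
from ctdnet.ctd_core import RETENTION, fixed_code_bits

from conftest import make_ids


# ---------------------------------------------------------------------------
# Independent oracle: a second, standalone implementation of the diffusion
# rule, written directly from its definition (anchors spread unit mass to
# unvisited neighbours by |weight|; a holder keeps RETENTION of what arrives
# and passes on the rest; dead ends and sub-threshold mass are retained).
# ---------------------------------------------------------------------------

def oracle_diffuse(net, anchors, visited, threshold=1e-4):
    scores = {}

    def push(node, mass, blocked):
        nbrs = [(v, abs(w)) for v, w in net.neighbors_weighted(node)
                if v not in visited and v not in blocked and w != 0]
        tot = sum(w for _, w in nbrs)
        if tot == 0:
            if node not in visited:
                scores[node] = scores.get(node, 0.0) + mass
            return
        for v, w in sorted(nbrs):
            m = mass * w / tot
            if m < threshold:
                scores[v] = scores.get(v, 0.0) + m
            else:
                scores[v] = scores.get(v, 0.0) + m * RETENTION
                push(v, m * (1 - RETENTION), blocked | {v})

    for a in sorted(anchors):
        push(a, 1.0, frozenset({a}))
    return scores


def oracle_information_content(net, s):
    """Replay the walk definition step by step, independently of ctd_core."""
    s = frozenset(s) & frozenset(net.nodes())
    n = net.n_nodes()
    best = math.inf
    for start in sorted(s):
        anchors, visited = {start}, {start}
        pos, last_found, found = 0, 0, {start}
        while s - found:
            scores = {v: m for v, m in
                      oracle_diffuse(net, anchors, visited).items() if m > 0}
            if not scores:
                break
            nxt = min(scores, key=lambda v: (-scores[v], v))
            visited.add(nxt)
            pos += 1
            if nxt in s:
                anchors.add(nxt)
                found.add(nxt)
                last_found = pos
        bits = math.log2(n) + last_found + len(s - found) * math.log2(n)
        best = min(best, bits)
    return best


# ---------------------------------------------------------------------------
# diffuse
# ---------------------------------------------------------------------------

class TestDiffuse:
    def test_star_center_splits_mass_equally(self):
        ids = ["c", "l1", "l2", "l3"]
        net = CoPerturbationNetwork(ids)
        for leaf in ids[1:]:
            net.add_edge("c", leaf, 0.5)
        scores = diffuse(net, {"c"}, {"c"})
        assert scores == pytest.approx({f"l{i}": 1 / 3 for i in (1, 2, 3)})

    def test_isolated_anchor_spreads_nothing(self):
        net = CoPerturbationNetwork(["a", "b"])
        assert diffuse(net, {"a"}, {"a"}) == {}

    def test_negative_weights_count_by_magnitude(self):
        net = CoPerturbationNetwork(["c", "p", "q"])
        net.add_edge("c", "p", -0.6)
        net.add_edge("c", "q", 0.3)
        scores = diffuse(net, {"c"}, {"c"})
        assert scores["p"] == pytest.approx(2 * scores["q"])

    def test_total_mass_bounded_by_anchor_count(self, ten_node_fixture_graph):
        net = ten_node_fixture_graph
        anchors = {"n00", "n03"}
        scores = diffuse(net, anchors, anchors)
        assert sum(scores.values()) <= len(anchors) + 1e-12

    def test_path_graph_matches_independent_oracle(self, path_graph):
        got = diffuse(path_graph, {"n00"}, {"n00"})
        want = oracle_diffuse(path_graph, {"n00"}, {"n00"})
        assert got == pytest.approx(want)

    def test_multi_anchor_matches_oracle_on_fixture(self,
                                                    ten_node_fixture_graph):
        anchors = {"n01", "n06"}
        got = diffuse(ten_node_fixture_graph, anchors, anchors | {"n02"})
        want = oracle_diffuse(ten_node_fixture_graph, anchors,
                              anchors | {"n02"})
        assert got == pytest.approx(want)

    def test_anchor_outside_network_rejected(self, path_graph):
        with pytest.raises(ValueError, match="not in network"):
            diffuse(path_graph, {"zz"}, {"zz"})


# ---------------------------------------------------------------------------
# adaptive_walk
# ---------------------------------------------------------------------------

class TestAdaptiveWalk:
    def test_triangle_finds_members_consecutively(self):
        net = CoPerturbationNetwork(["A", "B", "C"])
        net.add_edge("A", "B", 0.9)
        net.add_edge("B", "C", 0.8)
        net.add_edge("A", "C", 0.7)
        walk = adaptive_walk(net, {"A", "B", "C"}, "A")
        assert walk.ranking[0] == "A"
        assert walk.found_positions == (1, 2)

    def test_singleton_walk_is_trivial(self, path_graph):
        walk = adaptive_walk(path_graph, {"n02"}, "n02")
        assert walk.ranking == ("n02",)
        assert walk.found_positions == ()

    def test_start_must_be_member(self, path_graph):
        with pytest.raises(ValueError, match="not in the encoded set"):
            adaptive_walk(path_graph, {"n01"}, "n00")

    def test_ranking_has_no_repeats(self, ten_node_fixture_graph):
        s = {"n00", "n04", "n07"}
        walk = adaptive_walk(ten_node_fixture_graph, s, "n00")
        assert len(walk.ranking) == len(set(walk.ranking))

    def test_walk_stops_at_disconnected_remainder(self):
        # two components: n00-n01 and n02-n03; S spans both
        net = CoPerturbationNetwork(make_ids(4))
        net.add_edge("n00", "n01", 0.5)
        net.add_edge("n02", "n03", 0.5)
        walk = adaptive_walk(net, {"n00", "n01", "n03"}, "n00")
        assert "n03" not in walk.ranking
        assert walk.found_positions == (1,)


# ---------------------------------------------------------------------------
# information_content
# ---------------------------------------------------------------------------

class TestInformationContent:
    def test_singleton_costs_log2_n(self, clique_in_sparse):
        bits, walk = information_content(clique_in_sparse, {"n07"})
        assert bits == math.log2(16)
        assert walk.ranking == ("n07",)

    def test_clique_encodes_in_log2n_plus_k_minus_1(self, clique_in_sparse):
        bits, _ = information_content(clique_in_sparse, set(make_ids(4)))
        assert bits == math.log2(16) + 3

    def test_unreachable_members_cost_log2n_each(self):
        net = CoPerturbationNetwork(make_ids(8))
        net.add_edge("n00", "n01", 0.5)
        bits, _ = information_content(net, {"n00", "n01", "n05"})
        assert bits == pytest.approx(math.log2(8) + 1 + math.log2(8))

    def test_empty_set_rejected(self, path_graph):
        with pytest.raises(ValueError, match="empty"):
            information_content(path_graph, set())

    def test_all_size3_subsets_match_replay_oracle(self,
                                                   ten_node_fixture_graph):
        net = ten_node_fixture_graph
        for s in itertools.combinations(net.nodes(), 3):
            bits, _ = information_content(net, frozenset(s))
            assert bits == pytest.approx(oracle_information_content(net, s)), s

    def test_edge_inside_set_never_hurts(self, path_graph):
        # connecting two members directly can only speed up their discovery
        s = frozenset({"n00", "n02", "n05"})
        before, _ = information_content(path_graph, s)
        denser = CoPerturbationNetwork(path_graph.nodes(), path_graph.edges())
        denser.add_edge("n00", "n05", 0.8)
        after, _ = information_content(denser, s)
        assert after <= before + 1e-9


# ---------------------------------------------------------------------------
# ctd_pvalue
# ---------------------------------------------------------------------------

class TestCtdPvalue:
    def test_singleton_saves_no_bits(self, clique_in_sparse):
        res = ctd_pvalue(clique_in_sparse, {"n09"})
        assert res.bits_saved == 0.0
        assert res.p_value == 1.0

    def test_edgeless_network_gives_p_one(self):
        net = CoPerturbationNetwork(make_ids(8))
        res = ctd_pvalue(net, {"n00", "n01", "n05"})
        assert res.p_value == 1.0

    def test_clique_beats_scattered_nodes(self):
        ids = make_ids(32)
        net = CoPerturbationNetwork(ids)
        for a, b in itertools.combinations(ids[:5], 2):
            net.add_edge(a, b, 0.8)
        for a, b in zip(ids[5:], ids[6:]):
            net.add_edge(a, b, 0.3)
        net.add_edge(ids[4], ids[5], 0.2)
        clique_p = ctd_pvalue(net, set(ids[:5])).p_value
        scattered_p = ctd_pvalue(
            net, {ids[6], ids[12], ids[18], ids[24], ids[30]}).p_value
        assert clique_p < scattered_p
        assert clique_p < 0.01

    def test_optimal_subset_is_subset_and_p_capped(self,
                                                   ten_node_fixture_graph):
        s = frozenset(["n00", "n02", "n05", "n08"])
        res = ctd_pvalue(ten_node_fixture_graph, s)
        assert res.optimal_subset <= s
        assert 0.0 < res.p_value <= 1.0
        assert res.p_value == pytest.approx(
            min(1.0, 2.0 ** (-res.bits_saved)))

    def test_deterministic(self, ten_node_fixture_graph):
        s = frozenset(["n01", "n03", "n04", "n09"])
        r1 = ctd_pvalue(ten_node_fixture_graph, s)
        r2 = ctd_pvalue(ten_node_fixture_graph, s)
        assert r1 == r2

    def test_no_overlap_with_network_rejected(self, path_graph):
        with pytest.raises(ValueError, match="no scoreable nodes"):
            ctd_pvalue(path_graph, {"zz"})

    def test_bound_holds_exhaustively_on_fixture(self,
                                                 ten_node_fixture_graph):
        """#{S size k: bits_saved >= b} <= C(n,k)*2^-b at every achieved b."""
        net = ten_node_fixture_graph
        n = net.n_nodes()
        for k in (2, 4):
            saved = []
            for s in itertools.combinations(net.nodes(), k):
                bits, _ = information_content(net, frozenset(s))
                saved.append(fixed_code_bits(n, k) - bits)
            saved = np.array(saved)
            for b in np.unique(saved):
                if b <= 0:
                    continue
                count = int((saved >= b - 1e-9).sum())
                assert count <= len(saved) * 2.0 ** (-b) + 1e-6
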