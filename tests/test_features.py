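"""Data-source scoring and topological features, checked against closed
forms and exhaustive-summation oracles."""

import itertools
import math
import random

import networkx as nx
import pytest

from complexpred import (
    build_feature_table,
    deg,
    lit_jaccard,
    method_reliability,
    nbc,
    ppi_reliability,
    shared_adjustcd,
    string_filter,
)
from complexpred.netio import EvidenceRecord, OntologyAnnotation, ScoredPair
from tests.conftest import build_net


def make_cc(protein_terms):
    """Flat one-level ontology: every term is_a root."""
    dag = nx.DiGraph()
    dag.add_node("root")
    terms = {t for ts in protein_terms.values() for t in ts}
    direct = {}
    for t in terms:
        dag.add_edge(t, "root")
    for p, ts in protein_terms.items():
        for t in ts:
            direct.setdefault(t, set()).add(p)
    return OntologyAnnotation(dag, direct)


class TestMethodReliability:
    def test_fraction_of_colocalised_pairs(self):
        cc = make_cc({"A": {"t"}, "B": {"t"}, "C": {"t"}, "D": {"t"},
                      "E": {"u"}, "F": set(), "G": {"t"}, "H": set()})
        ev = [
            EvidenceRecord("A", "B", "tap", "p1"),   # share t
            EvidenceRecord("C", "D", "tap", "p2"),   # share t
            EvidenceRecord("A", "G", "tap", "p3"),   # share t
            EvidenceRecord("E", "F", "tap", "p4"),   # F unannotated
        ]
        rel = method_reliability(ev, cc, {"t", "u"})
        assert rel["tap"] == pytest.approx(0.75)

    def test_all_pairs_share_gives_one(self):
        cc = make_cc({"A": {"t"}, "B": {"t"}})
        ev = [EvidenceRecord("A", "B", "y2h", "p1")]
        assert method_reliability(ev, cc, {"t"})["y2h"] == 1.0

    def test_matches_brute_force_on_random_toy(self):
        rng = random.Random(7)
        prots = [f"P{i}" for i in range(10)]
        terms = ["t1", "t2", "t3"]
        assignment = {p: {rng.choice(terms)} if rng.random() < 0.8 else set()
                      for p in prots}
        cc = make_cc(assignment)
        ev = []
        for i in range(30):
            a, b = rng.sample(prots, 2)
            ev.append(EvidenceRecord(a, b, rng.choice(["m1", "m2"]), f"p{i}"))
        rel = method_reliability(ev, cc, set(terms))
        for method in ("m1", "m2"):
            pairs = {r.pair for r in ev if r.method == method}
            expect = sum(
                1 for a, b in pairs if assignment[a] & assignment[b]
            ) / len(pairs)
            assert rel[method] == pytest.approx(expect)


class TestPPIReliability:
    def test_repeat_detection_closed_form(self):
        ev = [EvidenceRecord("A", "B", "m", "p1"),
              EvidenceRecord("A", "B", "m", "p2")]
        net = ppi_reliability(ev, {"m": 0.5})
        assert net.edges["A", "B"]["weight"] == pytest.approx(1 - 0.5 ** 2)

    def test_two_methods_closed_form(self):
        ev = [EvidenceRecord("A", "B", "m1", "p1"),
              EvidenceRecord("A", "B", "m2", "p2")]
        net = ppi_reliability(ev, {"m1": 0.6, "m2": 0.5})
        assert net.edges["A", "B"]["weight"] == pytest.approx(1 - 0.4 * 0.5)

    def test_duplicate_publication_counted_once(self):
        ev = [EvidenceRecord("A", "B", "m", "pX"),
              EvidenceRecord("A", "B", "m", "pX")]
        net = ppi_reliability(ev, {"m": 0.5})
        assert net.edges["A", "B"]["weight"] == pytest.approx(0.5)

    def test_perfectly_reliable_method_saturates(self):
        ev = [EvidenceRecord("A", "B", "m", "p1")]
        assert ppi_reliability(ev, {"m": 1.0}).edges["A", "B"]["weight"] == 1.0

    def test_monotone_in_added_evidence(self):
        rel = {"m1": 0.3, "m2": 0.6}
        ev = [EvidenceRecord("A", "B", "m1", "p1")]
        w0 = ppi_reliability(ev, rel).edges["A", "B"]["weight"]
        ev.append(EvidenceRecord("A", "B", "m2", "p2"))
        w1 = ppi_reliability(ev, rel).edges["A", "B"]["weight"]
        assert w1 > w0 > 0


class TestStringFilter:
    @pytest.mark.parametrize("score,kept", [(0.50, False), (0.51, True), (0.9, True)])
    def test_strict_threshold(self, score, kept):
        net = string_filter([ScoredPair("A", "B", score)])
        assert net.has_edge("A", "B") == kept

    def test_empty_input(self):
        assert string_filter([]).number_of_edges() == 0


class TestLitJaccard:
    def test_partial_overlap(self):
        net = lit_jaccard({"a": {"p1", "p2", "p3"}, "b": {"p2", "p3", "p4"}})
        assert net.edges["a", "b"]["weight"] == pytest.approx(0.5)

    def test_identical_sets(self):
        net = lit_jaccard({"a": {"p1"}, "b": {"p1"}})
        assert net.edges["a", "b"]["weight"] == 1.0

    def test_disjoint_sets_no_edge(self):
        net = lit_jaccard({"a": {"p1"}, "b": {"p2"}})
        assert not net.has_edge("a", "b")


def random_weighted_graph(n, p, seed):
    rng = random.Random(seed)
    g = nx.Graph()
    nodes = [f"n{i}" for i in range(n)]
    g.add_nodes_from(nodes)
    for u, v in itertools.combinations(nodes, 2):
        if rng.random() < p:
            g.add_edge(u, v, weight=round(rng.random(), 3))
    return g


class TestDeg:
    def test_small_example(self):
        net = build_net({("a", "b"): 1, ("a", "c"): 1, ("b", "d"): 1})
        assert deg(net, ("a", "b")) == 2.0

    def test_isolated_pair(self):
        net = build_net({("a", "b"): 1})
        assert deg(net, ("a", "b")) == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_exhaustive_sum_oracle(self, seed):
        g = random_weighted_graph(8, 0.5, seed)
        for a, b in itertools.combinations(sorted(g.nodes), 2):
            expect = sum(
                d["weight"]
                for u in (a, b)
                for x, d in g.adj[u].items()
                if x not in (a, b)
            )
            assert deg(g, (a, b)) == pytest.approx(expect)


class TestNbc:
    def test_complete_neighbourhood_scores_one(self):
        net = build_net({("a", "c"): 1, ("a", "d"): 1, ("b", "c"): 1,
                         ("b", "d"): 1, ("c", "d"): 1})
        assert nbc(net, ("a", "b"), 10) == pytest.approx(1.0)

    def test_no_edges_among_neighbours(self):
        net = build_net({("a", "c"): 1, ("b", "d"): 1})
        assert nbc(net, ("a", "b"), 10) == 0.0

    def test_single_neighbour_degenerate(self):
        net = build_net({("a", "c"): 1, ("b", "c"): 1})
        assert nbc(net, ("a", "b"), 10) == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_exhaustive_oracle(self, seed):
        g = random_weighted_graph(8, 0.5, seed + 10)
        lam = 4
        for a, b in itertools.combinations(sorted(g.nodes), 2):
            nbrs = (set(g.adj[a]) | set(g.adj[b])) - {a, b}
            if len(nbrs) < 2:
                assert nbc(g, (a, b), lam) == 0.0
                continue
            total = sum(
                2 * d["weight"]
                for u, v, d in g.edges(data=True)
                if u in nbrs and v in nbrs
            )
            m = min(len(nbrs), lam)
            assert nbc(g, (a, b), lam) == pytest.approx(total / (m * (m - 1)))


def adjustcd_reference(net, iterations):
    """Independent re-implementation of the iterative AdjustCD recurrence,
    written directly from the formula with no shared code."""
    weights = {tuple(sorted((u, v))): d["weight"] for u, v, d in net.edges(data=True)}
    nodes = sorted(net.nodes)
    for _ in range(iterations):
        nbrs = {u: {} for u in nodes}
        for (u, v), w in weights.items():
            nbrs.setdefault(u, {})[v] = w
            nbrs.setdefault(v, {})[u] = w
        for u in list(nbrs):
            if u not in nodes:
                nodes.append(u)
        strength = {u: sum(nbrs.get(u, {}).values()) for u in nodes}
        navg = sum(strength.values()) / len(nodes)
        new = {}
        for u, v in itertools.combinations(sorted(nodes), 2):
            common = set(nbrs.get(u, {})) & set(nbrs.get(v, {}))
            if not common:
                continue
            num = sum(nbrs[u][x] + nbrs[v][x] for x in common)
            lam_u = max(0.0, navg - strength[u])
            lam_v = max(0.0, navg - strength[v])
            val = num / (strength[u] + lam_u + strength[v] + lam_v)
            if val > 0:
                new[(u, v)] = val
        weights = new
    return weights


class TestSharedAdjustCD:
    def test_no_shared_neighbour_absent(self):
        net = build_net({("a", "b"): 1, ("c", "d"): 1})
        assert ("a", "c") not in shared_adjustcd(net, 1)

    def test_symmetric_output_keys_canonical(self):
        net = build_net({("a", "c"): 1, ("b", "c"): 1, ("a", "b"): 0.5})
        scores = shared_adjustcd(net, 2)
        assert all(u < v for u, v in scores)

    @pytest.mark.parametrize("iterations", [1, 2])
    def test_matches_independent_recurrence(self, iterations):
        g = random_weighted_graph(8, 0.6, seed=3)
        ours = shared_adjustcd(g, iterations)
        ref = adjustcd_reference(g, iterations)
        assert set(ours) == set(ref)
        for pair in ref:
            assert ours[pair] == pytest.approx(ref[pair])

    def test_twin_nodes_score_near_maximum(self):
        # two nodes with identical neighbour sets in a unit-weight graph
        edges = {}
        for hub in ("u", "v"):
            for i in range(6):
                edges[(hub, f"n{i}")] = 1.0
        for i in range(6):
            edges[(f"n{i}", f"m{i}")] = 1.0
        net = build_net(edges)
        scores = shared_adjustcd(net, 1)
        assert scores[("u", "v")] == pytest.approx(max(scores.values()))


class TestFeatureTable:
    @pytest.fixture
    def nets(self):
        ppi = build_net({("a", "b"): 0.9, ("b", "c"): 0.8, ("a", "c"): 0.7})
        string = build_net({("a", "b"): 0.6, ("c", "d"): 0.9})
        lit = build_net({("a", "d"): 0.5})
        return ppi, string, lit

    def test_decomp_columns_ppi_only(self, nets):
        table = build_feature_table(nets[0], nets[1], nets[2], "DECOMP")
        assert list(table.columns) == ["PPI"]
        assert set(table.index) == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_swc_columns(self, nets):
        table = build_feature_table(*nets, "SWC")
        assert list(table.columns) == ["PPI", "STRING", "LIT", "SHARED_PPI"]
        # row exists for any pair scored by ≥1 source
        assert ("c", "d") in table.index and ("a", "d") in table.index

    def test_sss_has_thirteen_columns_iso_zero(self, nets):
        table = build_feature_table(*nets, "SSS")
        assert len(table.columns) == 13
        assert (table["ISO"] == 0).all()

    def test_unknown_approach_rejected(self, nets):
        with pytest.raises(ValueError, match="unknown approach"):
            build_feature_table(*nets, "XXX")

    def test_missing_values_are_zero(self, nets):
        table = build_feature_table(*nets, "SWC")
        assert table.loc[("c", "d"), "PPI"] == 0.0
        assert table.loc[("a", "b"), "LIT"] == 0.0
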