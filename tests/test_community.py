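"""Modularity and Louvain, validated against analytic cases, an exhaustive
small-graph oracle, and the independent networkx implementation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from networkx.algorithms.community import modularity as nx_modularity

from wardnet.build import SnapshotGraph
from wardnet.community import (
    brute_force_best,
    louvain,
    modularity,
    modularity_terms,
    random_graph_null,
)
from wardnet.errors import GraphError, UndefinedModularityError

from conftest import rand_bipartite, two_k22


def eight_node_fixture():
    """8-node bipartite toy with a fixed 3-community membership."""
    edges = {("wA", "u1"): 1, ("wA", "u2"): 1, ("wB", "u1"): 1, ("wB", "u2"): 1,
             ("wC", "u3"): 1, ("wD", "u3"): 1, ("wC", "u4"): 1, ("wB", "u3"): 1}
    g = SnapshotGraph(
        ward_nodes={"wA", "wB", "wC", "wD"},
        unit_nodes={"u1", "u2", "u3", "u4"},
        edges=edges, period_label="toy8",
    )
    membership = {"wA": 0, "wB": 0, "u1": 0, "u2": 0,
                  "wC": 1, "u3": 1, "wD": 2, "u4": 2}
    return g, membership


def matrix_formula_q(graph: SnapshotGraph, membership) -> float:
    """Independent oracle: Q = (1/2m) sum_ij (A_ij - d_i d_j / 2m) delta(c_i, c_j)."""
    nodes = graph.nodes
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for w, u in graph.edges:
        a[idx[w], idx[u]] = a[idx[u], idx[w]] = 1
    d = a.sum(axis=1)
    m2 = d.sum()
    c = np.array([membership[x] for x in nodes])
    delta = c[:, None] == c[None, :]
    return float(((a - np.outer(d, d) / m2) * delta).sum() / m2)


class TestModularity:
    def test_one_community_is_zero(self):
        g, _ = two_k22()
        q = modularity(g, {n: 0 for n in g.nodes})
        assert q == pytest.approx(0.0, abs=1e-15)

    def test_two_disconnected_blocks_give_half(self):
        g, mem = two_k22()
        assert modularity(g, mem) == pytest.approx(0.5, abs=1e-15)

    def test_term_by_term_oracle_on_eight_node_fixture(self):
        g, mem = eight_node_fixture()
        # independent term-by-term expansion of sum_c [L_c/m - (D_c/2m)^2]
        m = g.n_edges
        deg = g.degree()
        q_expected = 0.0
        for c in set(mem.values()):
            members = {n for n, cc in mem.items() if cc == c}
            l_c = sum(1 for w, u in g.edges if w in members and u in members)
            d_c = sum(deg[n] for n in members)
            q_expected += l_c / m - (d_c / (2 * m)) ** 2
        assert modularity(g, mem) == pytest.approx(q_expected, abs=1e-12)
        assert modularity(g, mem) == pytest.approx(matrix_formula_q(g, mem), abs=1e-12)

    def test_matches_networkx_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for i in range(20):
            g = rand_bipartite(rng, 4, 5, int(rng.integers(3, 15)))
            mem = {n: int(rng.integers(3)) for n in g.nodes}
            comms = [
                {n for n, c in mem.items() if c == k} for k in sorted(set(mem.values()))
            ]
            assert modularity(g, mem) == pytest.approx(
                nx_modularity(g.to_networkx(), comms), abs=1e-12
            )

    def test_zero_edge_graph_raises(self):
        g = SnapshotGraph(set(), set(), {}, "empty")
        with pytest.raises(UndefinedModularityError):
            modularity(g, {})

    def test_terms_invariants(self):
        g, mem = eight_node_fixture()
        t = modularity_terms(g, mem)
        assert sum(t.degree_sums.values()) == 2 * t.m
        assert sum(t.intra_edges.values()) <= t.m


class TestLouvain:
    def test_two_blocks_unique_optimum(self):
        g, mem = two_k22()
        p = louvain(g, seed=0)
        assert p.modularity == pytest.approx(0.5, abs=1e-12)
        # membership equals the blocks up to relabelling
        assert {frozenset(c) for c in p.communities().values()} == {
            frozenset({"wA", "wB", "u1", "u2"}), frozenset({"wC", "wD", "u3", "u4"})
        }

    def test_beats_singletons_and_stays_bounded(self):
        rng = np.random.default_rng(11)
        for i in range(25):
            g = rand_bipartite(rng, 5, 5, int(rng.integers(2, 20)))
            p = louvain(g, seed=i)
            singles = modularity(g, {n: k for k, n in enumerate(g.nodes)})
            assert p.modularity >= singles - 1e-12
            assert -0.5 - 1e-12 <= p.modularity <= 1.0
            # stored Q is consistent with a recomputation
            assert p.modularity == pytest.approx(modularity(g, p.membership), abs=1e-12)
            # contiguous community ids
            assert sorted(set(p.membership.values())) == list(range(p.n_communities))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        g = rand_bipartite(rng, 6, 6, 20)
        p1 = louvain(g, seed=123)
        p2 = louvain(g, seed=123)
        assert p1.membership == p2.membership and p1.modularity == p2.modularity

    def test_node_relabelling_leaves_q_unchanged(self, default_world):
        """Renaming every node of an (easy) planted graph does not change the
        modularity Louvain attains."""
        _, _, _, graphs = default_world
        g = graphs[0]
        relabel = {n: f"x{n}" for n in g.ward_nodes} | {n: f"y{n}" for n in g.unit_nodes}
        g2 = SnapshotGraph(
            ward_nodes={relabel[n] for n in g.ward_nodes},
            unit_nodes={relabel[n] for n in g.unit_nodes},
            edges={(relabel[w], relabel[u]): s for (w, u), s in g.edges.items()},
            period_label="relabelled",
        )
        q1 = louvain(g, seed=9).modularity
        q2 = louvain(g2, seed=9).modularity
        assert q1 == pytest.approx(q2, abs=1e-9)

    def test_zero_edge_graph_raises(self):
        g = SnapshotGraph({"w"}, {"u"}, {}, "no-edges")
        with pytest.raises(UndefinedModularityError):
            louvain(g, seed=0)


class TestBruteForce:
    def test_single_edge_optimum_is_one_community(self):
        g = SnapshotGraph({"w"}, {"u"}, {("w", "u"): 1}, "edge")
        p = brute_force_best(g)
        assert p.n_communities == 1 and p.modularity == pytest.approx(0.0, abs=1e-15)

    def test_two_blocks(self):
        g, mem = two_k22()
        p = brute_force_best(g)
        assert p.modularity == pytest.approx(0.5, abs=1e-12)

    def test_never_below_louvain_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for i in range(25):
            g = rand_bipartite(rng, 4, 4, int(rng.integers(2, 13)))
            assert (
                brute_force_best(g).modularity
                >= louvain(g, seed=i).modularity - 1e-12
            )

    def test_refuses_large_graphs(self):
        rng = np.random.default_rng(0)
        g = rand_bipartite(rng, 7, 7, 30)
        if g.n_nodes > 12:
            with pytest.raises(GraphError):
                brute_force_best(g)


class TestRandomNull:
    def test_complete_bipartite_null_degenerate(self):
        s = random_graph_null(3, 3, 9, n_reps=5, seed=0)
        assert s.sd == 0.0
        assert s.z_score(s.mean + 0.1) == np.inf

    def test_deterministic(self):
        s1 = random_graph_null(5, 6, 12, n_reps=3, seed=42)
        s2 = random_graph_null(5, 6, 12, n_reps=3, seed=42)
        assert np.array_equal(s1.samples, s2.samples)

    def test_infeasible_edge_count_rejected(self):
        with pytest.raises(GraphError):
            random_graph_null(2, 2, 5, n_reps=1, seed=0)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1), st.integers(3, 24))
def test_relabel_invariance_of_q(seed, perm_seed):
    """Permuting community ids never changes Q."""
    rng = np.random.default_rng(seed % 1000)
    g = rand_bipartite(rng, 4, 5, int(rng.integers(2, 18)))
    mem = {n: int(rng.integers(4)) for n in g.nodes}
    shift = {c: (c * 7 + perm_seed) % 97 for c in set(mem.values())}
    mem2 = {n: shift[c] for n, c in mem.items()}
    assert modularity(g, mem) == pytest.approx(modularity(g, mem2), abs=1e-12)
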