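"""Loop censuses against brute-force oracles, plus loop diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bqsnet import (
    GRN,
    GRNError,
    closure_additions,
    count_feedback_loops,
    count_incomplete_loops,
    count_simple_paths,
    critical_edges,
    find_chaotic_motifs,
    has_long_loop,
    loops_per_gene,
    qs_condition_report,
    stabilizing_pairs,
)
from conftest import tf_grn
from oracles import (
    brute_cycle_census,
    brute_incomplete_census,
    brute_path_census,
    random_digraph,
)


class TestFeedbackCensus:
    def test_triangle(self, triangle):
        census = count_feedback_loops(triangle)
        assert census[3] == 1
        assert census.total() == 1

    def test_complete_digraph_on_four(self):
        nodes = list("ABCD")
        g = GRN([(u, v) for u in nodes for v in nodes if u != v])
        census = count_feedback_loops(g, 6)
        assert {L: c for L, c in census.counts.items() if c} == {2: 6, 3: 8, 4: 6}

    def test_dag_has_no_loops(self):
        g = tf_grn([("A", "B"), ("A", "C"), ("B", "C"), ("C", "D")])
        assert count_feedback_loops(g).total() == 0

    def test_closing_a_hamiltonian_path_creates_one_cycle(self):
        n = 6
        edges = [(f"n{i}", f"n{i+1}") for i in range(n - 1)]
        g = tf_grn(edges + [(f"n{n-1}", "n0")])
        census = count_feedback_loops(g)
        assert census.total() == 1 and census[n] == 1

    def test_max_len_must_be_at_least_two(self, triangle):
        with pytest.raises(ValueError):
            count_feedback_loops(triangle, max_len=1)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        nodes, edges = random_digraph(rng, 6, 0.3)
        g = tf_grn(edges, nodes)
        mapping = {v: f"zz_{v}" for v in nodes}
        g2 = tf_grn([(mapping[u], mapping[v]) for u, v in edges],
                    [mapping[v] for v in nodes])
        assert count_feedback_loops(g).counts == count_feedback_loops(g2).counts


class TestPathsAndIncomplete:
    def test_chain_paths(self, chain):
        assert count_simple_paths(chain, 4) == {1: 2, 2: 1, 3: 0, 4: 0}

    def test_triangle_paths(self, triangle):
        counts = count_simple_paths(triangle, 3)
        assert counts[1] == 3 and counts[2] == 3

    def test_edgeless_graph(self):
        g = GRN([], nodes=list("ABC"), tf_set=list("ABC"))
        assert all(v == 0 for v in count_simple_paths(g, 5).values())

    def test_chain_incomplete(self, chain):
        assert count_incomplete_loops(chain)[2] == 1

    def test_triangle_two_paths_all_close(self, triangle):
        assert count_incomplete_loops(triangle)[2] == 0

    def test_non_tf_tail_excluded_from_census(self):
        # C has no out-edges, so with an inferred TF set the path stops at B
        g = GRN([("A", "B"), ("B", "C")])
        assert count_simple_paths(g, 3) == {1: 1, 2: 0, 3: 0}


class TestOracleEquivalence:
    """Implementation vs exhaustive vertex-sequence enumeration."""

    @pytest.mark.parametrize("seed", range(30))
    def test_random_digraphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        nodes, edges = random_digraph(rng, n, float(rng.uniform(0.1, 0.5)))
        g = tf_grn(edges, nodes)
        max_len = n
        assert count_feedback_loops(g, max_len).counts == brute_cycle_census(
            nodes, edges, max_len
        )
        assert count_simple_paths(g, max_len) == brute_path_census(
            nodes, edges, max_len
        )
        assert count_incomplete_loops(g, max_len).counts == brute_incomplete_census(
            nodes, edges, max_len
        )

    @pytest.mark.parametrize("seed", range(15))
    def test_census_identity(self, seed):
        """incomplete[L] = paths[L] - (L+1) * cycles[L+1] on random graphs."""
        rng = np.random.default_rng(100 + seed)
        nodes, edges = random_digraph(rng, 7, 0.3)
        g = tf_grn(edges, nodes)
        cycles = count_feedback_loops(g, 8).counts
        paths = count_simple_paths(g, 7)
        inc = count_incomplete_loops(g, 7).counts
        for L in range(2, 8):
            assert inc[L] == paths[L] - (L + 1) * cycles.get(L + 1, 0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_identity_property(self, graph_seed):
        rng = np.random.default_rng(graph_seed)
        nodes, edges = random_digraph(rng, 6, 0.35)
        g = tf_grn(edges, nodes)
        cycles = count_feedback_loops(g, 7).counts
        paths = count_simple_paths(g, 6)
        inc = count_incomplete_loops(g, 6).counts
        assert all(
            inc[L] == paths[L] - (L + 1) * cycles.get(L + 1, 0)
            for L in range(2, 7)
        )


class TestClosureAdditions:
    def brute(self, k):
        """Try all absent edges of a bare k-edge path; count loop-makers."""
        nodes = [f"p{i}" for i in range(k + 1)]
        edges = [(nodes[i], nodes[i + 1]) for i in range(k)]
        base = sum(
            c for L, c in brute_cycle_census(nodes, edges, k + 1).items() if L >= 3
        )
        hits = 0
        for u in nodes:
            for v in nodes:
                if u != v and (u, v) not in edges:
                    after = edges + [(u, v)]
                    total = sum(
                        c
                        for L, c in brute_cycle_census(nodes, after, k + 1).items()
                        if L >= 3
                    )
                    hits += total > base
        return hits

    @pytest.mark.parametrize("k", [2, 3, 4, 6])
    def test_matches_brute_force(self, k):
        assert closure_additions(k) == self.brute(k) == k * (k - 1) // 2

    def test_short_path_rejected(self):
        with pytest.raises(ValueError):
            closure_additions(1)


class TestLoopDiagnostics:
    def test_loops_per_gene_triangle(self, triangle):
        table, total = loops_per_gene(triangle)
        assert total == 1
        assert set(table.index) == {"A", "B", "C"}
        assert (table["percent_of_loops"] == 100.0).all()

    def test_loops_per_gene_disjoint_triangles(self, two_triangles_disjoint):
        table, total = loops_per_gene(two_triangles_disjoint)
        assert total == 2
        assert (table["loop_count"] == 1).all()
        assert (table["percent_of_loops"] == 50.0).all()

    def test_loops_per_gene_shared_node(self):
        g = tf_grn(
            [("X", "B"), ("B", "C"), ("C", "X"),
             ("X", "E"), ("E", "F"), ("F", "X")]
        )
        table, total = loops_per_gene(g)
        assert total == 2
        assert table.loc["X", "loop_count"] == 2
        assert table.drop("X")["loop_count"].eq(1).all()

    def test_loops_per_gene_empty_when_no_long_loops(self, chain):
        table, total = loops_per_gene(chain)
        assert total == 0 and table.empty

    def test_critical_edges_triangle(self, triangle):
        assert critical_edges(triangle) == set(triangle.edges)

    def test_critical_edges_disjoint_triangles_empty(self, two_triangles_disjoint):
        assert critical_edges(two_triangles_disjoint) == set()

    def test_critical_edges_shared_edge(self, two_triangles_shared_edge):
        assert critical_edges(two_triangles_shared_edge) == {("A", "B")}

    def test_critical_edges_need_a_long_loop(self, chain):
        with pytest.raises(GRNError):
            critical_edges(chain)

    def test_stabilizing_pairs_disjoint_triangles(self, two_triangles_disjoint):
        table = stabilizing_pairs(two_triangles_disjoint)
        best = table[table["residual_long_loops"] == 0]
        # exactly the cross-triangle pairs kill both loops
        assert len(best) == 9
        first = {"A", "B", "C"}
        assert all(
            (row.tf_a in first) != (row.tf_b in first)
            for row in best.itertuples()
        )

    def test_stabilizing_pairs_single_triangle(self, triangle):
        table = stabilizing_pairs(triangle)
        assert (table["residual_long_loops"] == 0).all()

    def test_stabilizing_pairs_shared_node_dominates(self):
        # X sits on two of three triangles: pairs with X rank best
        g = tf_grn(
            [("X", "B"), ("B", "C"), ("C", "X"),
             ("X", "E"), ("E", "F"), ("F", "X"),
             ("P", "Q"), ("Q", "R"), ("R", "P")]
        )
        table = stabilizing_pairs(g)
        best = table[table["residual_long_loops"] == 0]
        # only X (killing both its triangles) paired with a PQR node
        # removes every long loop; without X at least one survives
        assert len(best) == 3
        assert all("X" in (r.tf_a, r.tf_b) for r in best.itertuples())
        assert all(
            {r.tf_a, r.tf_b} & {"P", "Q", "R"} for r in best.itertuples()
        )

    def test_stabilizing_pairs_tie_break_lexicographic(self, triangle):
        table = stabilizing_pairs(triangle)
        assert list(table[["tf_a", "tf_b"]].itertuples(index=False, name=None)) == [
            ("A", "B"), ("A", "C"), ("B", "C")
        ]


class TestChaoticMotifs:
    def test_canonical_chaotic_triple(self):
        g = tf_grn(
            [("A", "B"), ("B", "A"), ("B", "C"), ("C", "B"), ("C", "A")]
        )
        assert find_chaotic_motifs(g) == [("A", "B", "C")]

    def test_plain_triangle_is_not_chaotic(self, triangle):
        assert find_chaotic_motifs(triangle) == []

    def test_dag_has_none(self):
        g = tf_grn([("A", "B"), ("B", "C"), ("A", "C")])
        assert find_chaotic_motifs(g) == []

    def test_fully_mutual_triangle_yields_one_instance_per_middle(self):
        # A<->B<->C<->A: each node serves once as the shared middle; the
        # two closing directions of a given middle are the same instance
        g = tf_grn(
            [("A", "B"), ("B", "A"), ("B", "C"), ("C", "B"),
             ("C", "A"), ("A", "C")]
        )
        hits = find_chaotic_motifs(g)
        assert len(hits) == 3
        assert {middle for _, middle, _ in hits} == {"A", "B", "C"}


class TestQSReport:
    def test_positive_self_loop_violates_condition_one(self):
        g = GRN([("A", "A"), ("A", "B")], signs={("A", "A"): "+"})
        report = qs_condition_report(g)
        assert report.positive_self_loops == ["A"]
        assert report.condition1_verdict == "violated"

    def test_negative_self_loop_passes(self):
        g = GRN([("A", "A"), ("A", "B")], signs={("A", "A"): "-"})
        report = qs_condition_report(g)
        assert report.condition1_verdict == "pass"

    def test_double_negative_two_loop_is_switch_like(self):
        g = tf_grn([("A", "B"), ("B", "A")])
        g = GRN(g.edges, tf_set=g.tf_set,
                signs={("A", "B"): "-", ("B", "A"): "-"})
        report = qs_condition_report(g)
        [loop] = report.two_node_loops
        assert loop["sign_class"] == "double-negative"
        assert loop["isolated"] is True
        assert report.condition2_verdict == "violated"

    def test_mixed_sign_two_loop_allowed(self):
        g = GRN([("A", "B"), ("B", "A")], tf_set=["A", "B"],
                signs={("A", "B"): "+", ("B", "A"): "-"})
        assert qs_condition_report(g).condition2_verdict == "pass"

    def test_unsigned_network_is_indeterminate(self):
        g = GRN([("A", "A"), ("A", "B"), ("B", "A")], tf_set=["A", "B"])
        report = qs_condition_report(g)
        assert report.condition1_verdict == "indeterminate"
        assert report.condition2_verdict == "indeterminate"
        [loop] = report.two_node_loops
        assert loop["sign_class"] == "unsigned"

    def test_two_loop_sharing_long_loop_not_isolated(self):
        g = tf_grn(
            [("A", "B"), ("B", "A"), ("A", "C"), ("C", "D"), ("D", "A")]
        )
        report = qs_condition_report(g)
        [loop] = report.two_node_loops
        assert loop["isolated"] is False
        assert report.condition3_verdict == "violated"

    def test_long_loop_free_network_passes_condition_three(self, chain):
        assert qs_condition_report(chain).condition3_verdict == "pass"


class TestHasLongLoop:
    def test_two_cycle_only_is_not_long(self):
        g = tf_grn([("A", "B"), ("B", "A")])
        assert not has_long_loop(g)

    def test_mutual_pair_chain_scc_without_long_cycle(self):
        # strongly connected triple {A,B,C} whose only cycles are 2-cycles
        g = tf_grn([("A", "B"), ("B", "A"), ("B", "C"), ("C", "B")])
        assert not has_long_loop(g)

    def test_triangle_detected(self, triangle):
        assert has_long_loop(triangle)
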