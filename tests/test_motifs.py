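"""Motif census, buffering classification, equiprobability grouping."""

import itertools

import numpy as np
import pytest

from bqsnet import (
    GRN,
    all_motif_classes,
    canonical_form,
    classify_buffering,
    enumerate_motifs,
    equiprobability_groups,
)
from bqsnet.motifs import _canonical_code, _string_to_code
from conftest import tf_grn
from oracles import brute_motif_additions, random_digraph


class TestClassification:
    def test_fan_out_is_buffered(self):
        mc = classify_buffering([("A", "B"), ("A", "C")])
        assert mc.destabilizing_additions == 0
        assert mc.category == "buffered"

    def test_fan_in_is_buffered(self):
        assert classify_buffering([("A", "C"), ("B", "C")]).category == "buffered"

    def test_chain_is_mono_unbuffered(self):
        mc = classify_buffering([("A", "B"), ("B", "C")])
        assert mc.destabilizing_additions == 1
        assert mc.category == "mono-unbuffered"

    def test_bifan_is_buffered(self):
        mc = classify_buffering([("A", "C"), ("A", "D"), ("B", "C"), ("B", "D")])
        assert mc.category == "buffered"
        assert mc.n_nodes == 4

    def test_feedforward_loop_is_mono_unbuffered(self):
        # stable (no cycle) but one addition (C->A) closes a 3-loop
        mc = classify_buffering([("A", "B"), ("B", "C"), ("A", "C")])
        assert mc.destabilizing_additions == 1
        assert mc.category == "mono-unbuffered"

    def test_three_cycle_is_unstable(self):
        mc = classify_buffering([("A", "B"), ("B", "C"), ("C", "A")])
        assert mc.category == "unstable"

    def test_four_chain_is_poly_unbuffered(self):
        # D->A closes a 4-loop, C->A a 3-loop, D->B a 3-loop
        mc = classify_buffering([("A", "B"), ("B", "C"), ("C", "D")])
        assert mc.destabilizing_additions == 3
        assert mc.category == "poly-unbuffered"

    def test_two_node_loop_inside_motif_is_not_long(self):
        # a mutual pair plus a spectator target: no >= 3 cycle yet
        mc = classify_buffering([("A", "B"), ("B", "A"), ("A", "C")])
        assert mc.category != "unstable"

    def test_size_other_than_3_or_4_rejected(self):
        with pytest.raises(ValueError):
            classify_buffering([("A", "B")])

    @pytest.mark.parametrize("size", [3, 4])
    def test_every_class_matches_brute_force(self, size):
        """Exhaustive check: every isomorphism class vs the edge-insertion
        oracle (insert each absent edge, recount >= 3-node cycles)."""
        for mc in all_motif_classes(size, connected_only=False):
            code, n = _string_to_code(mc.canonical_form)
            edge_set = {
                (i, j)
                for i in range(n)
                for j in range(n)
                if i != j and code >> (i * n + j) & 1
            }
            additions, unstable = brute_motif_additions(n, edge_set)
            assert mc.destabilizing_additions == additions
            assert (mc.category == "unstable") == unstable
            if not unstable:
                expected = (
                    "buffered" if additions == 0
                    else "mono-unbuffered" if additions == 1
                    else "poly-unbuffered"
                )
                assert mc.category == expected


class TestCanonicalForms:
    def test_isomorphic_labelings_share_form(self):
        a = canonical_form([("A", "B"), ("B", "C")])
        b = canonical_form([("X", "Z"), ("Q", "X")])  # Q->X->Z relabelled
        assert a == b

    def test_distinct_motifs_differ(self):
        assert canonical_form([("A", "B"), ("B", "C")]) != canonical_form(
            [("A", "B"), ("A", "C")]
        )

    def test_class_count_three_nodes(self):
        # 13 connected triads is the standard directed-triad census size
        assert len(all_motif_classes(3)) == 13

    def test_class_count_four_nodes(self):
        # 199 weakly connected 4-node digraphs (no self-loops)
        assert len(all_motif_classes(4)) == 199

    def test_placements_times_automorphisms(self):
        from bqsnet.motifs import _automorphisms

        for mc in all_motif_classes(3):
            code, n = _string_to_code(mc.canonical_form)
            assert mc.placements * _automorphisms(code, n) == 6


class TestCensus:
    def test_single_ffl(self):
        g = tf_grn([("A", "B"), ("B", "C"), ("A", "C")])
        table = enumerate_motifs(g, 3)
        assert table.total == 1
        assert table.table["observed_count"].iloc[0] == 1

    def test_complete_triad(self):
        nodes = list("ABC")
        g = tf_grn([(u, v) for u in nodes for v in nodes if u != v])
        table = enumerate_motifs(g, 3)
        assert table.total == 1
        assert table.table["n_edges"].iloc[0] == 6

    def test_disjoint_chain_and_fan(self):
        g = tf_grn(
            [("A", "B"), ("B", "C"), ("D", "E"), ("D", "F")]
        )
        table = enumerate_motifs(g, 3)
        assert table.total == 2
        forms = {canonical_form([("A", "B"), ("B", "C")]),
                 canonical_form([("D", "E"), ("D", "F")])}
        assert set(table.table.index) == forms
        assert (table.table["observed_count"] == 1).all()

    def test_census_is_induced(self):
        # triangle contains no chain instance: induced subgraph on the
        # single 3-subset is the 3-cycle itself
        g = tf_grn([("A", "B"), ("B", "C"), ("C", "A")])
        table = enumerate_motifs(g, 3)
        chain_form = canonical_form([("A", "B"), ("B", "C")])
        assert chain_form not in table.table.index

    def test_counts_sum_to_connected_subsets(self):
        rng = np.random.default_rng(11)
        nodes, edges = random_digraph(rng, 8, 0.25)
        g = tf_grn(edges, nodes)
        table = enumerate_motifs(g, 3)
        # independent count of weakly connected 3-subsets
        und = {v: set() for v in nodes}
        for u, v in edges:
            und[u].add(v)
            und[v].add(u)
        n_connected = 0
        for subset in itertools.combinations(nodes, 3):
            sub = set(subset)
            adj = {v: und[v] & sub for v in subset}
            seen = {subset[0]}
            stack = [subset[0]]
            while stack:
                for w in adj[stack.pop()]:
                    if w not in seen:
                        seen.add(w)
                        stack.append(w)
            n_connected += len(seen) == 3
        assert table.total == n_connected

    def test_isomorphism_invariance(self):
        rng = np.random.default_rng(5)
        nodes, edges = random_digraph(rng, 7, 0.3)
        g = tf_grn(edges, nodes)
        relabel = {v: f"r{v}" for v in nodes}
        g2 = tf_grn([(relabel[u], relabel[v]) for u, v in edges],
                    [relabel[v] for v in nodes])
        t1 = enumerate_motifs(g, 4).table["observed_count"]
        t2 = enumerate_motifs(g2, 4).table["observed_count"]
        assert t1.to_dict() == t2.to_dict()

    def test_only_tf_motifs_counted(self):
        # B->x edge leaves the TF subnetwork: no 3-node motif remains
        g = GRN([("A", "B"), ("B", "x")])  # TFs A, B
        assert enumerate_motifs(g, 3).total == 0


class TestEquiprobabilityGroups:
    def test_fan_in_and_fan_out_grouped(self):
        g = tf_grn([("A", "B"), ("B", "C"), ("D", "E"), ("D", "F"),
                    ("G", "I"), ("H", "I")])
        table = enumerate_motifs(g, 3)
        groups = equiprobability_groups(table)
        fan_out = canonical_form([("D", "E"), ("D", "F")])
        fan_in = canonical_form([("G", "I"), ("H", "I")])
        chain = canonical_form([("A", "B"), ("B", "C")])
        group_of = {
            form: key for key, forms in groups.items() for form in forms
        }
        assert group_of[fan_out] == group_of[fan_in]
        assert group_of[chain] != group_of[fan_out]

    def test_chain_has_six_placements_fans_three(self):
        chain = classify_buffering([("A", "B"), ("B", "C")])
        fan = classify_buffering([("A", "B"), ("A", "C")])
        assert chain.placements == 6
        assert fan.placements == 3
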