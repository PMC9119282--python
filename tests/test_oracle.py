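"""Unfolding, scenario enumeration/scoring, and the cubic DP oracle."""

import pytest

import netrecon as nr
from netrecon.netmodel import CapExceeded, StructureError
from netrecon.oracle import (
    best_scenario_bruteforce,
    count_root_leaf_paths,
    count_scenarios,
    dc_score_cubic,
    scenario_dc_score,
    scenario_dup_score,
    scenario_from_perfect,
    scenario_used,
    scenarios,
    unfold,
)

from conftest import instance_stream, ret_edges


class TestUnfold:
    def test_f1_leaf_multiset(self, F1):
        U = unfold(F1)
        assert sorted(U.label.values()) == ["a", "b", "b", "c"]
        assert U.is_tree()

    def test_tree_is_fixed_point(self, F2s_net):
        U = unfold(F2s_net)
        assert sorted(U.label.values()) == ["a", "b", "c", "d"]
        assert all(U.sigma[v] == v for v in U.children)

    def test_f4_chained_reticulations(self, F4):
        # H2 below H1: three copies of b after unfolding bottom-up
        U = unfold(F4)
        assert sorted(U.label.values()) == ["a", "b", "b", "b", "c"]
        assert U.is_tree()

    def test_path_correspondence(self):
        for _, N in instance_stream(401, 30, classes=("tree-child", "relaxed")):
            U = unfold(N)
            assert U.is_tree()
            assert count_root_leaf_paths(N) == len(U.leaves())
            # every reticulation origin appears as an outdegree-1 node
            rets = set(N.reticulations())
            semi = {U.sigma[v] for v in U.children if len(U.children[v]) == 1}
            assert rets <= semi

    def test_cap(self, F3):
        with pytest.raises(CapExceeded):
            unfold(F3, cap=1)


class TestScenarios:
    def test_counts(self, F1):
        U = unfold(F1)
        assert count_scenarios(nr.parse_gene_tree("(a,c);"), U) == 1
        assert count_scenarios(nr.parse_gene_tree("((a,b),c);"), U) == 2
        assert len(list(scenarios(nr.parse_gene_tree("((a,b),c);"), U))) == 2

    def test_missing_label(self, F1):
        with pytest.raises(StructureError, match="missing"):
            list(scenarios(nr.parse_gene_tree("(a,z);"), unfold(F1)))

    def test_count_matches_product_of_copies(self):
        for G, N in instance_stream(402, 15, scenario_cap=500):
            U = unfold(N)
            assert count_scenarios(G, U) == len(list(scenarios(G, U)))


class TestScenarioScoring:
    def test_unique_scenario_ac_on_f1(self, F1):
        G = nr.parse_gene_tree("(a,c);")
        U = unfold(F1)
        (xi,) = list(scenarios(G, U))
        tr = scenario_dc_score(G, F1, xi, U)
        assert tr.score == 0
        # both gene edges start with a type-I edge; one side passes a type-III
        types = [t for lst in tr.edge_types.values() for (_, _, t) in lst]
        assert types.count("I") >= 2 and "III" in types

    def test_bypass_marks_conflict_on_f1(self, F1):
        G = nr.parse_gene_tree("(a,c);")
        U = unfold(F1)
        (xi,) = list(scenarios(G, U))
        used = scenario_used(G, F1, xi, U)
        e_u, e_v = ret_edges(F1)
        assert used.potential == {e_u, e_v}
        assert used.direct == frozenset()
        assert used.has_conflict(F1)

    def test_direct_use_regular_on_f1(self, F1):
        G = nr.parse_gene_tree("((a,b),c);")
        U = unfold(F1)
        e_u, e_v = ret_edges(F1)
        best = None
        for xi in scenarios(G, U):
            tr = scenario_dc_score(G, F1, xi, U)
            if tr.score == 0 and not tr.used.has_conflict(F1):
                best = tr
        assert best is not None
        assert e_u in best.used.edges and e_v not in best.used.edges

    def test_lemma5_tree_reduction(self, F2a, F2s_net):
        U = unfold(F2s_net)
        (xi,) = list(scenarios(F2a, U))
        tr = scenario_dc_score(F2a, F2s_net, xi, U)
        assert tr.score == nr.dc_cost(F2a, nr.displayed_trees(F2s_net)[0].tree) == 0

    def test_dup_scores(self, F1):
        U = unfold(F1)
        G = nr.parse_gene_tree("((a,b),c);")
        assert min(scenario_dup_score(G, F1, xi, U) for xi in scenarios(G, U)) == 0
        N2 = nr.parse_enewick("(a,b);")
        G2 = nr.parse_gene_tree("((a,a),b);")
        U2 = unfold(N2)
        (xi2,) = list(scenarios(G2, U2))
        assert scenario_dup_score(G2, N2, xi2, U2) == 1


class TestBruteForce:
    def test_examples(self, F1, F2a, F2s_net):
        s, _, reg = best_scenario_bruteforce(nr.parse_gene_tree("(a,c);"), F1, "DC")
        assert (s, reg) == (0, False)
        s, _, reg = best_scenario_bruteforce(nr.parse_gene_tree("((a,b),c);"), F1, "DC")
        assert (s, reg) == (0, True)
        s, _, _ = best_scenario_bruteforce(F2a, F2s_net, "DC")
        assert s == 0

    def test_cap(self, F1):
        with pytest.raises(CapExceeded):
            best_scenario_bruteforce(nr.parse_gene_tree("((a,b),c);"), F1, "DC", cap=1)


class TestCubicDP:
    def test_examples(self, F1, F2a, F2s_net):
        assert dc_score_cubic(nr.parse_gene_tree("(a,c);"), F1) == 0
        assert dc_score_cubic(nr.parse_gene_tree("((a,b),c);"), F1) == 0
        assert dc_score_cubic(F2a, F2s_net) == 0

    def test_matches_bruteforce(self):
        for G, N in instance_stream(403, 40, classes=("tree-child",), scenario_cap=1000):
            bf, _, _ = best_scenario_bruteforce(G, N, "DC")
            assert dc_score_cubic(G, N) == bf


class TestPerfectSetScenarios:
    def test_xi_y_props(self, F1):
        """DC(G,N_Y) >= score(xi_Y), equal iff xi_Y regular."""
        G = nr.parse_gene_tree("(a,c);")
        U = unfold(F1)
        for Y in nr.perfect_sets(F1):
            xi = scenario_from_perfect(G, U, Y)
            tr = scenario_dc_score(G, F1, xi, U)
            cost = nr.dc_cost(G, nr.display(F1, Y).tree)
            assert cost >= tr.score
            assert (cost == tr.score) == (not tr.used.has_conflict(F1))

    def test_xi_y_props_random(self):
        # full label coverage: the lower bound is tight exactly for regular
        # scenarios
        for G, N in instance_stream(
            404, 20, classes=("tree-child",), r_range=(1, 4),
            style_cycle=("R1", "R3"), scenario_cap=2000,
        ):
            U = unfold(N)
            for Y in nr.perfect_sets(N):
                xi = scenario_from_perfect(G, U, Y)
                tr = scenario_dc_score(G, N, xi, U)
                cost = nr.dc_cost(G, nr.display(N, Y).tree)
                assert cost >= tr.score
                assert (cost == tr.score) == (not tr.used.has_conflict(N))

    def test_xi_y_lower_bound_with_partial_labels(self):
        # when the gene tree misses labels, a regular xi_Y may still bypass
        # an edge of Y (its sibling is never directly used), so only the
        # bound and the "equality implies regular" direction survive
        for G, N in instance_stream(
            405, 12, classes=("tree-child",), r_range=(1, 4),
            style_cycle=("R2",), scenario_cap=2000,
        ):
            U = unfold(N)
            for Y in nr.perfect_sets(N):
                xi = scenario_from_perfect(G, U, Y)
                tr = scenario_dc_score(G, N, xi, U)
                cost = nr.dc_cost(G, nr.display(N, Y).tree)
                assert cost >= tr.score
                if cost == tr.score:
                    assert not tr.used.has_conflict(N)
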