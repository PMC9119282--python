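"""Perfect sets, displayed trees, pruning, and their structural identities."""

import itertools
from collections import Counter

import numpy as np
import pytest

import netrecon as nr
from netrecon.displayed import (
    display,
    displayed_trees,
    perfect_sets,
    prune_edge,
    sibling_edge,
)
from netrecon.netmodel import CapExceeded, StructureError

from conftest import canon, instance_stream, ret_edges


class TestSiblingEdge:
    def test_involution_f1(self, F1):
        e1, e2 = ret_edges(F1)
        assert sibling_edge(F1, e1) == e2
        assert sibling_edge(F1, e2) == e1

    def test_f4_chain(self, F4):
        # H2's parents are H1 and w
        h2 = [r for r in F4.reticulations() if all(len(F4.children[p]) == 1 or True for p in F4.parents[r])]
        for r in F4.reticulations():
            p, q = F4.parents[r]
            assert sibling_edge(F4, (p, r)) == (q, r)

    def test_non_reticulation_edge_rejected(self, F1):
        root_edge = next(iter(F1.edges()))
        if not F1.is_reticulation(root_edge[1]):
            with pytest.raises(StructureError):
                sibling_edge(F1, root_edge)


class TestPerfectSets:
    def test_counts(self, F1, F3, F2s_net):
        assert len(list(perfect_sets(F1))) == 2
        assert len(list(perfect_sets(F3))) == 4
        assert list(perfect_sets(F2s_net)) == [frozenset()]

    def test_each_set_is_one_edge_per_reticulation(self, F3):
        for Y in perfect_sets(F3):
            heads = [h for _, h in Y]
            assert sorted(heads) == F3.reticulations()


class TestDisplay:
    def test_f1_both_trees(self, F1):
        e_u, e_v = ret_edges(F1)
        assert display(F1, {e_u}).newick == canon("((a,b),c);")
        assert display(F1, {e_v}).newick == canon("(a,(b,c));")

    def test_f4_with_dead_reticulation(self, F4):
        # choosing H2's non-H1 parent edge detaches H1's only child; H1 is
        # then pruned as an unlabeled leaf whichever of its in-edges is kept
        (h1,) = [r for r in F4.reticulations() if F4.children[r] == (max(F4.reticulations()),)
                 or F4.children[r] in [(c,) for c in F4.reticulations()]]
        (h2,) = F4.children[h1]
        (w_edge,) = [(p, h2) for p in F4.parents[h2] if p != h1]
        for p in F4.parents[h1]:
            dt = display(F4, {(p, h1), w_edge})
            assert dt.newick == canon("(a,(b,c));")

    def test_not_perfect_raises(self, F1, F3):
        e_u, e_v = ret_edges(F1)
        with pytest.raises(StructureError):
            display(F1, {e_u, e_v})
        with pytest.raises(StructureError):
            display(F3, set())

    def test_display_covers_all_labels(self):
        for _, N in instance_stream(210, 30, classes=("tree-child", "relaxed")):
            for Y in perfect_sets(N):
                dt = display(N, Y)
                assert sorted(dt.tree.leaf_labels()) == sorted(N.labels())


class TestPruneEdge:
    def test_f1(self, F1):
        e_u, e_v = ret_edges(F1)
        assert canon(nr.serialize(prune_edge(F1, e_v))) == canon("((a,b),c);")
        assert canon(nr.serialize(prune_edge(F1, e_u))) == canon("(a,(b,c));")

    def test_f3_locality(self, F3):
        # pruning in one blob leaves the other blob's displayed trees intact
        h2_edges = [e for e in ret_edges(F3) if e[1] == F3.reticulations()[1]]
        pruned = prune_edge(F3, h2_edges[0])
        assert pruned.n_reticulations() == 1
        trees = {d.newick for d in displayed_trees(pruned)}
        full = {d.newick for d in displayed_trees(F3)}
        assert trees <= full

    def test_class_preserved(self):
        for _, N in instance_stream(211, 30, classes=("tree-child",)):
            e = N.reticulation_edges()[0]
            rep = nr.validate(prune_edge(N, e))
            assert rep.is_tree_child
        for _, N in instance_stream(212, 30, classes=("relaxed",)):
            e = N.reticulation_edges()[0]
            rep = nr.validate(prune_edge(N, e))
            assert rep.is_relaxed
            assert rep.r == N.n_reticulations() - 1 or rep.r < N.n_reticulations()


class TestDisplayedTrees:
    def test_f1(self, F1):
        trees = displayed_trees(F1, dedupe=True)
        assert sorted(d.newick for d in trees) == sorted([canon("((a,b),c);"), canon("(a,(b,c));")])

    def test_f4_four_sets_two_topologies(self, F4):
        assert len(displayed_trees(F4)) == 4
        assert len(displayed_trees(F4, dedupe=True)) == 2

    def test_distinct_bound_2_pow_r(self):
        for _, N in instance_stream(213, 20, r_range=(2, 3), classes=("tree-child",)):
            assert len(displayed_trees(N, dedupe=True)) <= 2 ** N.n_reticulations()

    def test_cap(self, F3):
        with pytest.raises(CapExceeded):
            displayed_trees(F3, cap=1)

    def test_dedupe_subset_of_full(self):
        for _, N in instance_stream(214, 15, classes=("tree-child", "relaxed")):
            full = {d.newick for d in displayed_trees(N)}
            deduped = {d.newick for d in displayed_trees(N, dedupe=True)}
            assert deduped == full


class TestTheorem19Identity:
    """Pruning either sibling edge partitions the displayed trees.

    The multiset of displayed trees (one per perfect set) of N equals the
    disjoint union over N_e and N_e'; as topology *sets* only the union
    identity holds (distinct switchings can induce the same tree)."""

    def test_multiset_identity_tree_child(self):
        for _, N in instance_stream(215, 25, r_range=(1, 5), classes=("tree-child",)):
            e = N.reticulation_edges()[0]
            e2 = sibling_edge(N, e)
            full = Counter(d.newick for d in displayed_trees(N))
            part = Counter(d.newick for d in displayed_trees(prune_edge(N, e2)))
            part += Counter(d.newick for d in displayed_trees(prune_edge(N, e)))
            assert full == part

    def test_union_identity_relaxed(self):
        for _, N in instance_stream(216, 15, classes=("relaxed",)):
            e = N.reticulation_edges()[0]
            e2 = sibling_edge(N, e)
            full = {d.newick for d in displayed_trees(N)}
            union = {d.newick for d in displayed_trees(prune_edge(N, e2))} | {
                d.newick for d in displayed_trees(prune_edge(N, e))
            }
            assert full == union


class TestContractionConfluence:
    def test_rule_order_does_not_matter(self, F1, F4):
        nets = [F1, F4] + [N for _, N in instance_stream(217, 10, classes=("tree-child", "relaxed"))]
        rng = np.random.default_rng(0)
        for N in nets:
            for Y in perfect_sets(N):
                ref = display(N, Y).newick
                for _ in range(3):
                    order = tuple(rng.permutation(["prune", "splice", "rootdrop"]))
                    assert display(N, Y, rule_order=order).newick == ref
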