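"""Displayed trees of a phylogenetic network.

A *perfect set* (switching) Y keeps exactly one incoming edge per
reticulation; removing the other reticulation edges and contracting
degree-restricted nodes yields the species tree N_Y *displayed* by N.
For tree-child networks the removal alone already leaves a semi-binary
tree on X; relaxed networks additionally require deleting unlabeled
out-degree-zero nodes (a reticulation whose only child edge was removed).

Contraction is a three-rule rewriting system applied to a fixed point:

  prune     delete an unlabeled node of outdegree 0 with its in-edges;
  splice    contract an indegree-1/outdegree-1 node;
  rootdrop  delete a root of outdegree 1, promoting its child.

The rules are confluent on our inputs (asserted by tests, not assumed);
``_contract`` takes an explicit priority order so tests can randomize it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .netmodel import CapExceeded, GeneTree, PhyloNetwork, StructureError, serialize

__all__ = [
    "DisplayedTree",
    "sibling_edge",
    "perfect_sets",
    "display",
    "prune_edge",
    "displayed_trees",
]

Edge = tuple[int, int]


@dataclass(frozen=True)
class DisplayedTree:
    """A species tree displayed by a network, with the switching inducing it."""

    tree: GeneTree
    perfect_set: frozenset
    newick: str  # canonical form; equality of topologies is string equality


def sibling_edge(net: PhyloNetwork, e: Edge) -> Edge:
    """The unique other edge sharing ``e``'s head reticulation."""
    tail, head = e
    if not net.is_reticulation(head) or tail not in net.parents[head]:
        raise StructureError(f"{e} is not a reticulation edge")
    p, q = net.parents[head]
    return (q, head) if tail == p else (p, head)


def perfect_sets(net: PhyloNetwork):
    """All 2^r switchings: reticulations by node id, first parent first."""
    rets = net.reticulations()
    choice_lists = [[(p, r) for p in net.parents[r]] for r in rets]
    for combo in itertools.product(*choice_lists):
        yield frozenset(combo)


# ---------------------------------------------------------------------------
# contraction engine
# ---------------------------------------------------------------------------

_DEFAULT_ORDER = ("prune", "splice", "rootdrop")


class _Mutable:
    """Working copy of a network during edge deletion / contraction."""

    def __init__(self, net: PhyloNetwork):
        self.children = {v: list(cs) for v, cs in net.children.items()}
        self.parents = {v: list(ps) for v, ps in net.parents.items()}
        self.label = dict(net.label)
        self.root = net.root
        self.origin = dict(net.edge_origin)

    def remove_edge(self, a: int, b: int):
        self.children[a].remove(b)
        self.parents[b].remove(a)
        self.origin.pop((a, b), None)

    def delete_node(self, v: int):
        for p in list(self.parents[v]):
            self.remove_edge(p, v)
        del self.children[v]
        del self.parents[v]

    def splice(self, v: int):
        """Contract an indegree-1/outdegree-1 node; keeps the lower edge's origin."""
        (p,) = self.parents[v]
        (c,) = self.children[v]
        low_origin = self.origin.get((v, c))
        self.remove_edge(p, v)
        self.remove_edge(v, c)
        del self.children[v]
        del self.parents[v]
        self.children[p].append(c)
        self.parents[c].append(p)
        if low_origin is not None:
            self.origin[(p, c)] = low_origin

    def rootdrop(self):
        old = self.root
        (c,) = self.children[old]
        self.remove_edge(old, c)
        del self.children[old]
        del self.parents[old]
        self.root = c


def _contract(m: _Mutable, order=_DEFAULT_ORDER):
    """Apply the three rewrite rules to a fixed point, honoring ``order``."""
    changed = True
    while changed:
        changed = False
        for rule in order:
            if rule == "prune":
                dead = [
                    v
                    for v in m.children
                    if not m.children[v] and v not in m.label and v != m.root
                ]
                for v in dead:
                    m.delete_node(v)
                    changed = True
                if dead:
                    break
            elif rule == "splice":
                hit = next(
                    (
                        v
                        for v in m.children
                        if len(m.parents[v]) == 1 and len(m.children[v]) == 1
                    ),
                    None,
                )
                if hit is not None:
                    m.splice(hit)
                    changed = True
                    break
            elif rule == "rootdrop":
                if len(m.children.get(m.root, ())) == 1:
                    m.rootdrop()
                    changed = True
                    break


def _check_perfect(net: PhyloNetwork, Y) -> None:
    per_ret: dict[int, int] = {}
    for tail, head in Y:
        if not net.is_reticulation(head) or tail not in net.parents[head]:
            raise StructureError(f"({tail},{head}) is not a reticulation edge")
        per_ret[head] = per_ret.get(head, 0) + 1
    rets = net.reticulations()
    if sorted(per_ret) != rets or any(per_ret[r] != 1 for r in rets):
        raise StructureError("set is not perfect: need exactly one incoming edge per reticulation")


def display(net: PhyloNetwork, Y, *, rule_order=_DEFAULT_ORDER) -> DisplayedTree:
    """The species tree N_Y induced by the perfect set ``Y``."""
    Y = frozenset(Y)
    _check_perfect(net, Y)
    m = _Mutable(net)
    for e in net.reticulation_edges():
        if e not in Y:
            m.remove_edge(*e)
    _contract(m, rule_order)
    children = {v: tuple(cs) for v, cs in m.children.items()}
    tree = GeneTree(children, m.label, m.root)
    for v in tree.nodes():
        if tree.children[v] and len(tree.children[v]) != 2:
            raise StructureError("display did not produce a binary tree")
    if set(tree.leaf_labels()) != net.labels() or len(tree.leaves()) != len(net.label):
        raise StructureError("display did not produce a tree on Lab(N)")
    return DisplayedTree(tree=tree, perfect_set=Y, newick=serialize(tree))


def prune_edge(net: PhyloNetwork, e: Edge, *, rule_order=_DEFAULT_ORDER) -> PhyloNetwork:
    """The network N_e: remove reticulation edge ``e``, then contract.

    The head (now indegree 1) and tail (now outdegree 1) are contracted, any
    cascade of dead unlabeled nodes is pruned (relevant for relaxed
    networks), and a unary root is dropped.  The result has r-1
    reticulations; edge origins are propagated so its reticulation edges
    remain identified with the input network's.
    """
    tail, head = e
    if not net.is_reticulation(head) or tail not in net.parents[head]:
        raise StructureError(f"{e} is not a reticulation edge")
    m = _Mutable(net)
    m.remove_edge(tail, head)
    _contract(m, rule_order)
    children = {v: tuple(cs) for v, cs in m.children.items()}
    out = PhyloNetwork(children, m.label, m.root, edge_origin=m.origin)
    return out


def displayed_trees(net: PhyloNetwork, dedupe: bool = False, cap: int = 16) -> list[DisplayedTree]:
    """One displayed tree per perfect set; with ``dedupe`` distinct topologies only."""
    r = net.n_reticulations()
    if r > cap:
        raise CapExceeded(f"network has {r} reticulations, enumeration cap is {cap}")
    out = [display(net, Y) for Y in perfect_sets(net)]
    if dedupe:
        seen: dict[str, DisplayedTree] = {}
        for dt in out:
            seen.setdefault(dt.newick, dt)
        out = list(seen.values())
    return out
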