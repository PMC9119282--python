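"""Classic gene-tree / species-tree reconciliation.

Costs are computed under the lca-mapping M: leaves map to the same-label
leaf of S and an internal gene node maps to the lca of its children's
images.  The deep coalescence cost counts extra gene lineages,

    DC(G,S) = sum over <v,w> in E(G) of (||M(v),M(w)|| - 1),

where ||.,.|| is the number of edges on the (unique, directed) path between
two comparable nodes of S; per-edge terms of -1 occur where M(v)=M(w) but
the total is nonnegative for binary trees with one-to-one labels.  The
duplication cost counts internal gene nodes mapping onto the image of one
of their children.  DC-up additionally charges the path from S's root down
to M(G.root); it is the per-tree summand the level-k solver minimizes over
displayed trees.
"""

from __future__ import annotations

from .displayed import DisplayedTree, display
from .netmodel import GeneTree, PhyloNetwork, StructureError

__all__ = ["LcaMapping", "lca_mapping", "dc_cost", "dup_cost", "dc_up_cost", "as_species_tree"]


class UnmappableLeafError(StructureError):
    pass


def as_species_tree(S) -> GeneTree:
    """Coerce a species-tree argument: GeneTree, DisplayedTree, or r=0 network."""
    if isinstance(S, GeneTree):
        return S
    if isinstance(S, DisplayedTree):
        return S.tree
    if isinstance(S, PhyloNetwork):
        if S.n_reticulations() != 0:
            raise StructureError("species tree argument has reticulations; solve ODT instead")
        return display(S, frozenset()).tree
    raise TypeError(f"not a species tree: {S!r}")


class LcaMapping:
    """The lca-mapping M: V(G) -> V(S) with a path-length accessor.

    ``path_len(v, w)`` is defined for comparable nodes only (v an ancestor
    of w or vice versa); calling it on incomparable nodes is a programming
    error, matching its use under the monotone M.
    """

    def __init__(self, G: GeneTree, S: GeneTree):
        self.G = G
        self.S = S
        labels = set(S.leaf_labels())
        if len(labels) != len(S.leaves()):
            raise StructureError("species tree labels must be one-to-one")
        missing = set(G.leaf_labels()) - labels
        if missing:
            raise UnmappableLeafError(f"unmappable leaf labels: {sorted(missing)}")

        self.depth = {S.root: 0}
        for v in S.postorder()[::-1]:
            for c in S.children[v]:
                self.depth[c] = self.depth[v] + 1
        leaf_of = {S.label[v]: v for v in S.leaves()}

        self.map: dict[int, int] = {}
        for g in G.postorder():
            if G.is_leaf(g):
                self.map[g] = leaf_of[G.label[g]]
            else:
                a, b = (self.map[c] for c in G.children[g])
                self.map[g] = self._lca(a, b)

    def _lca(self, a: int, b: int) -> int:
        S, depth = self.S, self.depth
        while depth[a] > depth[b]:
            a = S.parent[a]
        while depth[b] > depth[a]:
            b = S.parent[b]
        while a != b:
            a, b = S.parent[a], S.parent[b]
        return a

    def __getitem__(self, g: int) -> int:
        return self.map[g]

    def path_len(self, v: int, w: int) -> int:
        """||v,w||: number of edges between comparable nodes of S."""
        d = self.depth[w] - self.depth[v]
        if d < 0:
            return self.path_len(w, v)
        return d


def lca_mapping(G: GeneTree, S) -> LcaMapping:
    return LcaMapping(G, as_species_tree(S))


def dc_cost(G: GeneTree, S) -> int:
    M = lca_mapping(G, S)
    return sum(M.path_len(M[v], M[w]) - 1 for v, w in G.edges())


def dup_cost(G: GeneTree, S) -> int:
    M = lca_mapping(G, S)
    return sum(
        1
        for g in G.internal_nodes()
        if any(M[g] == M[c] for c in G.children[g])
    )


def dc_up_cost(G: GeneTree, S) -> int:
    """DC(G,S) plus the root path term ||M(G.root), S.root||."""
    M = lca_mapping(G, S)
    dc = sum(M.path_len(M[v], M[w]) - 1 for v, w in G.edges())
    return dc + M.depth[M[G.root]]
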