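"""Rooted binary gene trees and phylogenetic networks.

A *gene tree* is a rooted binary tree whose leaves carry species labels;
labels may repeat (MUL-trees).  A *phylogenetic network* is a rooted binary
DAG whose leaves are labeled one-to-one with species and whose internal
nodes are either *tree nodes* (indegree <= 1, outdegree 2) or
*reticulations* (indegree 2, outdegree 1) modelling hybridization, HGT or
recombination.  Two network classes matter downstream:

* tree-child   -- every non-leaf node has at least one non-reticulation child;
* relaxed      -- every node has at most one reticulation child (a strict
                  superset of tree-child: a reticulation's child may itself
                  be a reticulation).

The module also provides extended-Newick I/O (``#H`` hybrid tags) and the
biconnected-component ("blob") decomposition used by the level-k solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "GeneTree",
    "PhyloNetwork",
    "ClassReport",
    "Blob",
    "BlobDecomposition",
    "ParseError",
    "StructureError",
    "CapExceeded",
    "parse_gene_tree",
    "parse_enewick",
    "serialize",
    "validate",
    "decompose",
]


class ParseError(ValueError):
    """Malformed (extended) Newick input; carries the offending position."""

    def __init__(self, message: str, pos: int | None = None):
        if pos is not None:
            message = f"{message} (at position {pos})"
        super().__init__(message)
        self.pos = pos


class StructureError(ValueError):
    """Input violates the structural contract of the requested type."""


class CapExceeded(RuntimeError):
    """A resource cap (reticulation count, scenario count) was exceeded."""


# ---------------------------------------------------------------------------
# tokenizer / raw parser shared by trees and networks
# ---------------------------------------------------------------------------

_SPECIAL = set("(),;:#")


def _tokenize(text: str):
    """Yield (kind, value, pos); kinds: punct, name, tag, length."""
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c in "(),;":
            yield ("punct", c, i)
            i += 1
        elif c == "#":
            j = i + 1
            while j < n and text[j] not in _SPECIAL and not text[j].isspace():
                j += 1
            if j == i + 1:
                raise ParseError("empty hybrid tag", i)
            yield ("tag", text[i + 1 : j], i)
            i = j
        elif c == ":":
            j = i + 1
            while j < n and text[j] not in _SPECIAL and not text[j].isspace():
                j += 1
            yield ("length", text[i + 1 : j], i)
            i = j
        else:
            j = i
            while j < n and text[j] not in _SPECIAL and not text[j].isspace():
                j += 1
            yield ("name", text[i:j], i)
            i = j


class _RawNode:
    __slots__ = ("children", "name", "tag", "pos")

    def __init__(self, pos):
        self.children: list[_RawNode] = []
        self.name: str | None = None
        self.tag: str | None = None
        self.pos = pos


def _parse_raw(text: str) -> _RawNode:
    toks = list(_tokenize(text))
    if not toks:
        raise ParseError("empty input", 0)
    k = 0

    def peek():
        return toks[k] if k < len(toks) else ("punct", "", len(text))

    def subtree() -> _RawNode:
        nonlocal k
        kind, val, pos = peek()
        node = _RawNode(pos)
        if kind == "punct" and val == "(":
            k += 1
            node.children.append(subtree())
            while True:
                kind, val, pos = peek()
                if kind == "punct" and val == ",":
                    k += 1
                    node.children.append(subtree())
                elif kind == "punct" and val == ")":
                    k += 1
                    break
                else:
                    raise ParseError("expected ',' or ')'", pos)
        # optional name, tag, branch length (length ignored)
        kind, val, pos = peek()
        if kind == "name":
            node.name = val
            k += 1
            kind, val, pos = peek()
        if kind == "tag":
            node.tag = val
            k += 1
            kind, val, pos = peek()
        if kind == "length":
            k += 1
        return node

    root = subtree()
    kind, val, pos = peek()
    if not (kind == "punct" and val == ";"):
        raise ParseError("expected terminating ';'", pos)
    if k + 1 != len(toks):
        raise ParseError("trailing input after ';'", toks[k + 1][2])
    return root


# ---------------------------------------------------------------------------
# gene trees
# ---------------------------------------------------------------------------


class GeneTree:
    """Rooted binary MUL-tree; node ids are stable ints in input order."""

    def __init__(self, children: dict[int, tuple[int, ...]], label: dict[int, str], root: int):
        self.children = children
        self.label = label
        self.root = root
        self.parent: dict[int, int] = {}
        for v, cs in children.items():
            for c in cs:
                self.parent[c] = v

    # -- accessors ----------------------------------------------------------
    def nodes(self):
        return self.children.keys()

    def edges(self):
        for v, cs in self.children.items():
            for c in cs:
                yield (v, c)

    def num_edges(self) -> int:
        return len(self.children) - 1

    def leaves(self):
        return [v for v, cs in self.children.items() if not cs]

    def internal_nodes(self):
        return [v for v, cs in self.children.items() if cs]

    def is_leaf(self, v) -> bool:
        return not self.children[v]

    def leaf_labels(self) -> list[str]:
        return [self.label[v] for v in self.leaves()]

    def postorder(self) -> list[int]:
        out, stack = [], [self.root]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.children[v])
        out.reverse()
        return out

    def subtree_nodes(self, v) -> list[int]:
        out, stack = [], [v]
        while stack:
            w = stack.pop()
            out.append(w)
            stack.extend(self.children[w])
        return out

    def subtree_labels(self, v) -> set[str]:
        return {self.label[w] for w in self.subtree_nodes(v) if not self.children[w]}

    def subtree(self, v) -> "GeneTree":
        """The subtree G|v as its own GeneTree (node ids preserved)."""
        keep = self.subtree_nodes(v)
        children = {w: self.children[w] for w in keep}
        label = {w: self.label[w] for w in keep if not self.children[w]}
        return GeneTree(children, label, v)

    def __len__(self):
        return len(self.children)

    def __repr__(self):
        return f"GeneTree({serialize(self)!r})"


def parse_gene_tree(text: str) -> GeneTree:
    """Parse a rooted Newick string into a :class:`GeneTree`.

    Branch lengths and internal labels are accepted and ignored; repeated
    leaf labels are legal (MUL-trees).  Non-binary nodes are rejected.
    """
    raw = _parse_raw(text)
    children: dict[int, tuple[int, ...]] = {}
    label: dict[int, str] = {}
    counter = 0

    def build(r: _RawNode) -> int:
        nonlocal counter
        if r.tag is not None:
            raise ParseError("hybrid tag in gene tree", r.pos)
        me = counter
        counter += 1
        children[me] = ()
        if r.children:
            if len(r.children) != 2:
                raise ParseError("non-binary gene tree", r.pos)
            children[me] = tuple(build(c) for c in r.children)
        else:
            if r.name is None:
                raise ParseError("unlabeled leaf in gene tree", r.pos)
            label[me] = r.name
        return me

    root = build(raw)
    return GeneTree(children, label, root)


# ---------------------------------------------------------------------------
# phylogenetic networks
# ---------------------------------------------------------------------------


class PhyloNetwork:
    """Rooted binary DAG with reticulations.

    ``edge_origin`` maps every reticulation edge to its counterpart in the
    network the user originally supplied; pruning operations (module
    ``displayed``) propagate it so solver results can be expressed in the
    input network's edge space.
    """

    def __init__(
        self,
        children: dict[int, tuple[int, ...]],
        label: dict[int, str],
        root: int,
        edge_origin: dict[tuple[int, int], tuple[int, int]] | None = None,
        name: dict[int, str] | None = None,
    ):
        self.children = children
        self.label = label
        self.name = name or {}  # optional display names of internal nodes
        self.root = root
        self.parents: dict[int, tuple[int, ...]] = {v: () for v in children}
        for v, cs in children.items():
            for c in cs:
                self.parents[c] = self.parents[c] + (v,)
        if edge_origin is None:
            edge_origin = {e: e for e in self.reticulation_edges()}
        self.edge_origin = edge_origin

    # -- accessors ----------------------------------------------------------
    def nodes(self):
        return self.children.keys()

    def edges(self):
        for v, cs in self.children.items():
            for c in cs:
                yield (v, c)

    def num_edges(self) -> int:
        return sum(len(cs) for cs in self.children.values())

    def is_leaf(self, v) -> bool:
        return not self.children[v]

    def is_reticulation(self, v) -> bool:
        return len(self.parents[v]) == 2

    def leaves(self):
        return [v for v in self.children if self.is_leaf(v)]

    def reticulations(self) -> list[int]:
        return sorted(v for v in self.children if self.is_reticulation(v))

    def tree_nodes(self) -> list[int]:
        """Non-reticulation internal nodes (the root included)."""
        return [v for v in self.children if self.children[v] and not self.is_reticulation(v)]

    def reticulation_edges(self) -> list[tuple[int, int]]:
        return sorted((p, r) for r in self.children if self.is_reticulation(r) for p in self.parents[r])

    def labels(self) -> set[str]:
        return set(self.label.values())

    def n_reticulations(self) -> int:
        return sum(1 for v in self.children if self.is_reticulation(v))

    def topological_order(self) -> list[int]:
        """Root first; every node after all of its parents."""
        indeg = {v: len(self.parents[v]) for v in self.children}
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            for c in self.children[v]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    stack.append(c)
        if len(order) != len(self.children):
            raise StructureError("cycle in network")
        return order

    def subnetwork(self, v: int) -> "PhyloNetwork":
        """The sub-DAG induced by all nodes reachable from ``v``."""
        keep = set()
        stack = [v]
        while stack:
            w = stack.pop()
            if w in keep:
                continue
            keep.add(w)
            stack.extend(self.children[w])
        children = {w: self.children[w] for w in keep}
        label = {w: l for w, l in self.label.items() if w in keep}
        origin = {e: o for e, o in self.edge_origin.items() if e[0] in keep and e[1] in keep}
        return PhyloNetwork(children, label, v, origin)

    def __len__(self):
        return len(self.children)

    def __repr__(self):
        return f"PhyloNetwork({serialize(self)!r})"


def parse_enewick(text: str) -> PhyloNetwork:
    """Parse an extended-Newick string (``#H`` hybrid tags) into a network.

    The same tag may occur several times and denotes one node; exactly one
    occurrence may carry the hybrid node's child subtree.  Both ``lbl#H1``
    and bare ``#H1`` forms are accepted; branch lengths are ignored.
    """
    raw = _parse_raw(text)

    children: dict[int, list[int]] = {}
    label: dict[int, str] = {}
    name: dict[int, str] = {}
    tag_id: dict[str, int] = {}
    tag_has_subtree: dict[str, bool] = {}
    counter = 0

    def build(r: _RawNode) -> int:
        nonlocal counter
        if r.tag is not None:
            if r.tag in tag_id:
                me = tag_id[r.tag]
            else:
                me = counter
                counter += 1
                children[me] = []
                tag_id[r.tag] = me
                tag_has_subtree[r.tag] = False
                name[me] = r.name if r.name else f"#{r.tag}"
            if r.children:
                if tag_has_subtree[r.tag]:
                    raise ParseError(f"hybrid tag #{r.tag} carries more than one child subtree", r.pos)
                tag_has_subtree[r.tag] = True
                for c in r.children:
                    children[me].append(build(c))
            return me
        me = counter
        counter += 1
        children[me] = []
        if r.children:
            if r.name:
                name[me] = r.name
            for c in r.children:
                children[me].append(build(c))
        else:
            if r.name is None:
                raise ParseError("unlabeled leaf", r.pos)
            label[me] = r.name
        return me

    root = build(raw)

    # parent multiplicities
    nparents = {v: 0 for v in children}
    for v, cs in children.items():
        for c in cs:
            nparents[c] += 1
    for tag, v in tag_id.items():
        if nparents[v] != 2:
            raise ParseError(f"hybrid tag #{tag} has {nparents[v]} parents, expected 2")
        if len(children[v]) != 1:
            raise ParseError(f"hybrid node #{tag} must have exactly one child")
    # structural checks
    lbls = list(label.values())
    if len(set(lbls)) != len(lbls):
        dup = sorted({l for l in lbls if lbls.count(l) > 1})
        raise ParseError(f"duplicate leaf labels: {', '.join(dup)}")
    for v, cs in children.items():
        if len(cs) == 2 and cs[0] == cs[1]:
            raise ParseError(f"parallel edges into node {cs[0]} are not supported")
        if cs:
            expect = 1 if nparents[v] == 2 else 2
            if len(cs) != expect:
                raise ParseError(f"node {v} has outdegree {len(cs)}, expected {expect} (non-binary network)")
        elif v not in label:
            raise ParseError(f"unlabeled leaf node {v}")
        if nparents[v] > 2:
            raise ParseError(f"node {v} has indegree {nparents[v]} > 2")
    net = PhyloNetwork({v: tuple(cs) for v, cs in children.items()}, label, root, name=name)
    net.topological_order()  # raises on cycle
    return net


# ---------------------------------------------------------------------------
# canonical serialization
# ---------------------------------------------------------------------------


def _canon_expansion(net: PhyloNetwork) -> dict[int, tuple[str, str]]:
    """Per-node (min leaf label, canonical unfolded form) below it.

    Reticulations are expanded through, so the pair identifies the
    root-leaf path structure below a node; children are ordered by the
    lexicographically smallest descendant leaf label, ties by the full
    canonical string.
    """
    key: dict[int, tuple[str, str]] = {}
    for v in reversed(net.topological_order()):
        cs = net.children[v]
        if not cs:
            key[v] = (net.label[v], net.label[v])
        elif len(cs) == 1:
            key[v] = key[cs[0]]
        else:
            ordered = sorted((key[c] for c in cs))
            key[v] = (ordered[0][0], "(" + ",".join(k[1] for k in ordered) + ")")
    return key


def serialize(obj: GeneTree | PhyloNetwork) -> str:
    """Canonical (extended) Newick.

    Children are ordered by the lexicographically smallest descendant leaf
    label (ties broken by the full canonical subtree form); a hybrid node's
    subtree is attached at its first printed occurrence; branch lengths are
    never emitted.  ``parse(serialize(x))`` is isomorphic to ``x`` and
    isomorphism can be tested by string equality.
    """
    if isinstance(obj, GeneTree):
        def render(v: int) -> tuple[str, str, str]:
            cs = obj.children[v]
            if not cs:
                lbl = obj.label[v]
                return (lbl, lbl, lbl)
            ordered = sorted((render(c) for c in cs))
            text = "(" + ",".join(r[2] for r in ordered) + ")"
            return (ordered[0][0], text, text)

        return render(obj.root)[2] + ";"

    net = obj
    key = _canon_expansion(net)
    hyb_no: dict[int, int] = {}

    def render(v: int) -> str:
        cs = sorted(net.children[v], key=lambda c: key[c])
        if net.is_reticulation(v):
            if v in hyb_no:
                return f"#H{hyb_no[v]}"
            hyb_no[v] = len(hyb_no) + 1
            inner = render(cs[0])
            return f"({inner})#H{hyb_no[v]}"
        if not cs:
            return net.label[v]
        return "(" + ",".join(render(c) for c in cs) + ")"

    return render(net.root) + ";"


# ---------------------------------------------------------------------------
# class validation and blob decomposition
# ---------------------------------------------------------------------------


@dataclass
class ClassReport:
    is_binary: bool
    is_acyclic: bool
    labels_one_to_one: bool
    is_tree_child: bool
    is_relaxed: bool
    level: int
    r: int


def validate(net: PhyloNetwork) -> ClassReport:
    """Classify a parsed network; failures are reported, never raised."""
    is_binary = True
    for v in net.children:
        ind, outd = len(net.parents[v]), len(net.children[v])
        if v == net.root:
            ok = ind == 0 and outd == 2
        elif net.is_reticulation(v):
            ok = outd == 1
        elif outd == 0:
            ok = ind == 1
        else:
            ok = ind == 1 and outd == 2
        if not ok:
            is_binary = False
    try:
        net.topological_order()
        is_acyclic = True
    except StructureError:
        is_acyclic = False
    lbls = [net.label[v] for v in net.leaves()]
    labels_one_to_one = len(set(lbls)) == len(lbls) and len(lbls) == len(net.label)

    is_tree_child = all(
        any(not net.is_reticulation(c) for c in net.children[v])
        for v in net.children
        if net.children[v]
    )
    is_relaxed = all(
        sum(1 for c in net.children[v] if net.is_reticulation(c)) <= 1 for v in net.children
    )
    dec = decompose(net)
    return ClassReport(
        is_binary=is_binary,
        is_acyclic=is_acyclic,
        labels_one_to_one=labels_one_to_one,
        is_tree_child=is_tree_child,
        is_relaxed=is_relaxed,
        level=dec.level,
        r=net.n_reticulations(),
    )


@dataclass
class Blob:
    """A nontrivial biconnected component of the underlying undirected graph."""

    nodes: frozenset
    edges: frozenset  # directed edges of N inside the blob
    root: int  # unique member with no ancestor in the blob
    n_reticulations: int


@dataclass
class BlobDecomposition:
    blobs: list[Blob]
    edge_to_blob: dict[tuple[int, int], int]  # directed edge -> blob index
    level: int
    bc_tree: nx.DiGraph = field(repr=False)


def decompose(net: PhyloNetwork) -> BlobDecomposition:
    """Blob decomposition and the quotient tree bc(N).

    Biconnectivity is computed on the undirected underlying graph; trivial
    components (cut edges) are not blobs.  Each blob is annotated with its
    root (the unique member all of whose parents lie outside the blob) and
    its reticulation count; ``level`` is the maximum count over blobs.
    """
    ug = nx.Graph()
    ug.add_nodes_from(net.nodes())
    ug.add_edges_from(net.edges())
    blobs: list[Blob] = []
    edge_to_blob: dict[tuple[int, int], int] = {}
    for comp_edges in nx.biconnected_component_edges(ug):
        comp_edges = list(comp_edges)
        if len(comp_edges) < 2:
            continue
        nodes = frozenset(v for e in comp_edges for v in e)
        directed = frozenset(
            (a, b) if b in net.children[a] else (b, a) for a, b in comp_edges
        )
        roots = [v for v in nodes if all(p not in nodes for p in net.parents[v])]
        assert len(roots) == 1, "blob must have a unique root"
        # a reticulation's two parent edges always lie on an undirected cycle,
        # so a reticulation is never a blob root and belongs to exactly one blob
        nret = sum(1 for v in nodes if net.is_reticulation(v))
        idx = len(blobs)
        blobs.append(Blob(nodes=nodes, edges=directed, root=roots[0], n_reticulations=nret))
        for e in directed:
            edge_to_blob[e] = idx

    # quotient tree: contract each blob; nodes outside blobs keep identity.
    # A node that is a non-root member of some blob is represented by that
    # blob (a cut vertex is a non-root member of at most one blob).
    rep: dict[int, tuple] = {}
    for i, b in enumerate(blobs):
        for v in b.nodes:
            if v != b.root:
                rep[v] = ("blob", i)
    for i, b in enumerate(blobs):
        rep.setdefault(b.root, ("node", b.root))
    bc = nx.DiGraph()
    for v in net.nodes():
        bc.add_node(rep.get(v, ("node", v)))
    for a, b in net.edges():
        ra, rb = rep.get(a, ("node", a)), rep.get(b, ("node", b))
        if ra != rb:
            bc.add_edge(ra, rb)
    level = max((b.n_reticulations for b in blobs), default=0)
    return BlobDecomposition(blobs=blobs, edge_to_blob=edge_to_blob, level=level, bc_tree=bc)
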