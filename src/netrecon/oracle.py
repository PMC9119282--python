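"""Ground-truth machinery for small instances.

Everything here is exponential (or cubic) and exists to pin down the
efficient dynamic programs by independent computation:

* ``unfold`` materializes the unfolded network N-hat: each reticulation's
  subtree is duplicated bottom-up until a (semi-binary) tree remains whose
  root-leaf paths correspond one-to-one to those of N; ``sigma`` maps
  every copy back to its origin in N.
* ``scenarios`` enumerates all label-preserving maps from gene leaves to
  leaves of N-hat; each visited N-hat edge is classified into types I-IV
  and the deep-coalescence score counts types I and II, minus one per gene
  edge.  Reticulation edges are *directly used* when a type I/II edge maps
  onto them and *potentially used* when their sibling is bypassed (type
  III); a scenario whose used set contains no sibling pair is *regular*.
* ``dc_score_cubic`` is an independent O(|G||N|^3) dynamic program over
  pairs of network nodes, with the path-cost helper ``pi`` that counts the
  minimal number of type I/II edges between two comparable nodes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

from .netmodel import CapExceeded, GeneTree, PhyloNetwork, StructureError

__all__ = [
    "UnfoldedNetwork",
    "UsedEdgeSet",
    "ScenarioScore",
    "unfold",
    "scenarios",
    "scenario_mapping",
    "scenario_dc_score",
    "scenario_used",
    "scenario_dup_score",
    "best_scenario_bruteforce",
    "dc_score_cubic",
    "count_root_leaf_paths",
]

Edge = tuple[int, int]


@dataclass(frozen=True)
class UsedEdgeSet:
    """Reticulation edges used by a scenario, split by how they are used."""

    direct: frozenset
    potential: frozenset

    @property
    def edges(self) -> frozenset:
        return self.direct | self.potential

    def conflicts(self, net: PhyloNetwork) -> list[tuple[Edge, Edge]]:
        """Sibling pairs contained in the set, ordered by reticulation id."""
        out = []
        for r in net.reticulations():
            p, q = net.parents[r]
            e1, e2 = (p, r), (q, r)
            if e1 in self.edges and e2 in self.edges:
                out.append(tuple(sorted((e1, e2))))
        return out

    def has_conflict(self, net: PhyloNetwork) -> bool:
        return bool(self.conflicts(net))


class UnfoldedNetwork:
    """The semi-binary tree N-hat with its origin map sigma."""

    def __init__(self, net: PhyloNetwork, children, parent, root, sigma, label):
        self.net = net
        self.children = children  # dict[int, list[int]]
        self.parent = parent  # dict[int, int]; root absent
        self.root = root
        self.sigma = sigma  # dict[int, int] -> V(N)
        self.label = label  # leaves only
        self.depth = {root: 0}
        order = [root]
        for v in order:
            for c in children[v]:
                self.depth[c] = self.depth[v] + 1
                order.append(c)
        self.preorder = order
        # copy indices per label, in preorder (the a1, c3 subscripts)
        self.leaf_copies: dict[str, list[int]] = {}
        self.copy_index: dict[int, int] = {}
        for v in order:
            if v in label:
                lst = self.leaf_copies.setdefault(label[v], [])
                lst.append(v)
                self.copy_index[v] = len(lst)

    def leaves(self):
        return [v for v in self.preorder if v in self.label]

    def is_tree(self) -> bool:
        return all(len(self.children[v]) <= 2 for v in self.children) and len(
            self.parent
        ) == len(self.children) - 1

    def lca(self, a: int, b: int) -> int:
        while self.depth[a] > self.depth[b]:
            a = self.parent[a]
        while self.depth[b] > self.depth[a]:
            b = self.parent[b]
        while a != b:
            a, b = self.parent[a], self.parent[b]
        return a

    def __len__(self):
        return len(self.children)


def unfold(net: PhyloNetwork, cap: int = 8) -> UnfoldedNetwork:
    """Unfold all reticulations, bottom-most first; N-hat may be exponential."""
    r = net.n_reticulations()
    if r > cap:
        raise CapExceeded(f"unfolding cap exceeded: r={r} > {cap}")
    children = {v: list(cs) for v, cs in net.children.items()}
    parents = {v: list(ps) for v, ps in net.parents.items()}
    sigma = {v: v for v in net.children}
    label = dict(net.label)
    counter = max(net.children, default=0) + 1

    topo = net.topological_order()
    rets = [v for v in topo if net.is_reticulation(v)]
    for ret in reversed(topo):  # reversed topological: bottom-most first
        if ret not in rets:
            continue
        # copy the subtree rooted at ret (a tree by construction order)
        def copy_subtree(v: int) -> int:
            nonlocal counter
            nv = counter
            counter += 1
            sigma[nv] = sigma[v]
            if v in label:
                label[nv] = label[v]
            children[nv] = []
            parents[nv] = []
            for c in children[v]:
                nc = copy_subtree(c)
                children[nv].append(nc)
                parents[nc] = [nv]
            return nv

        p = parents[ret][-1]  # detach from the last-listed parent
        new_root = copy_subtree(ret)
        children[p][children[p].index(ret)] = new_root
        parents[ret].remove(p)
        parents[new_root] = [p]

    parent = {v: ps[0] for v, ps in parents.items() if ps}
    return UnfoldedNetwork(net, children, parent, net.root, sigma, label)


def surviving_leaves(U: UnfoldedNetwork, Y) -> list[int]:
    """Leaves of N-hat reachable without traversing a removed edge.

    An N-hat edge is removed when its sigma-image is a reticulation edge
    outside the perfect set Y; the survivors realize N-hat_Y as a mask over
    the shared unfolding (subtrees hanging below removed edges drop out).
    """
    Y = frozenset(Y)
    removed = set(U.net.reticulation_edges()) - Y
    out, stack = [], [U.root]
    while stack:
        v = stack.pop()
        if v in U.label:
            out.append(v)
        for c in U.children[v]:
            if (U.sigma[v], U.sigma[c]) not in removed:
                stack.append(c)
    return out


def scenario_from_perfect(G: GeneTree, U: UnfoldedNetwork, Y) -> dict:
    """The scenario xi_Y: each gene leaf maps to the unique surviving copy
    of its label in N-hat_Y (well-defined for perfect Y on a tree-child
    network)."""
    by_label: dict[str, list[int]] = {}
    for v in surviving_leaves(U, Y):
        by_label.setdefault(U.label[v], []).append(v)
    xi = {}
    for g in sorted(G.leaves()):
        copies = by_label.get(G.label[g], [])
        if len(copies) != 1:
            raise StructureError(
                f"label {G.label[g]!r} has {len(copies)} surviving copies; Y not perfect?"
            )
        xi[g] = copies[0]
    return xi


def count_root_leaf_paths(net: PhyloNetwork) -> int:
    """Number of root-leaf paths in N, by DP on the DAG (= |L(N-hat)|)."""
    paths = {}
    for v in reversed(net.topological_order()):
        paths[v] = 1 if net.is_leaf(v) else sum(paths[c] for c in net.children[v])
    return paths[net.root]


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


def scenarios(G: GeneTree, U: UnfoldedNetwork):
    """All scenarios: the Cartesian product over per-leaf copy lists."""
    leaves = sorted(G.leaves())
    pools = []
    for g in leaves:
        copies = U.leaf_copies.get(G.label[g])
        if not copies:
            raise StructureError(f"label {G.label[g]!r} missing from network")
        pools.append(copies)
    for combo in itertools.product(*pools):
        yield dict(zip(leaves, combo))


def count_scenarios(G: GeneTree, U: UnfoldedNetwork) -> int:
    n = 1
    for g in G.leaves():
        n *= len(U.leaf_copies.get(G.label[g], ()))
    return n


def scenario_mapping(G: GeneTree, U: UnfoldedNetwork, xi: dict) -> dict:
    """The lca-extension M_xi: V(G) -> V(N-hat)."""
    M = {}
    for g in G.postorder():
        if G.is_leaf(g):
            M[g] = xi[g]
        else:
            a, b = (M[c] for c in G.children[g])
            M[g] = U.lca(a, b)
    return M


@dataclass
class ScenarioScore:
    score: int
    edge_types: dict  # gene edge -> list of (a, b, type) visited N-hat edges
    bypassed: list  # reticulation edges of N bypassed by type-III visits
    direct: frozenset
    potential: frozenset

    @property
    def used(self) -> UsedEdgeSet:
        return UsedEdgeSet(direct=self.direct, potential=self.potential)


def _trace(G: GeneTree, U: UnfoldedNetwork, xi: dict) -> ScenarioScore:
    net = U.net
    M = scenario_mapping(G, U, xi)
    score = 0
    edge_types: dict = {}
    bypassed: list = []
    direct, potential = set(), set()
    for v, w in G.edges():
        top, bot = M[v], M[w]
        path = []
        x = bot
        while x != top:
            p = U.parent[x]
            path.append((p, x))
            x = p
        path.reverse()
        kappa = 0
        typed = []
        for a, b in path:
            if a == top:
                t = "I"
            elif len(U.children[a]) == 1:
                t = "IV"
            else:
                sib = next(c for c in U.children[a] if c != b)
                if net.is_reticulation(U.sigma[sib]):
                    t = "III"
                    bp = (U.sigma[a], U.sigma[sib])
                    bypassed.append(bp)
                    p2, q2 = net.parents[bp[1]]
                    potential.add((q2, bp[1]) if bp[0] == p2 else (p2, bp[1]))
                else:
                    t = "II"
            if t in ("I", "II"):
                kappa += 1
                if net.is_reticulation(U.sigma[b]):
                    direct.add((U.sigma[a], U.sigma[b]))
            typed.append((a, b, t))
        edge_types[(v, w)] = typed
        score += kappa - 1
    return ScenarioScore(
        score=score,
        edge_types=edge_types,
        bypassed=bypassed,
        direct=frozenset(direct),
        potential=frozenset(potential),
    )


def scenario_dc_score(G: GeneTree, N: PhyloNetwork, xi: dict, U: UnfoldedNetwork | None = None) -> ScenarioScore:
    """DC score of one scenario, with the full per-edge type trace."""
    if U is None:
        U = unfold(N)
    return _trace(G, U, xi)


def scenario_used(G: GeneTree, N: PhyloNetwork, xi: dict, U: UnfoldedNetwork | None = None) -> UsedEdgeSet:
    if U is None:
        U = unfold(N)
    return _trace(G, U, xi).used


def scenario_dup_score(G: GeneTree, N: PhyloNetwork, xi: dict, U: UnfoldedNetwork | None = None) -> int:
    """Number of gene nodes mapping (under M_xi) onto a child's image."""
    if U is None:
        U = unfold(N)
    M = scenario_mapping(G, U, xi)
    return sum(1 for g in G.internal_nodes() if any(M[g] == M[c] for c in G.children[g]))


def best_scenario_bruteforce(
    G: GeneTree, N: PhyloNetwork, cost: str = "DC", cap: int = 10**6
):
    """Exact scenario-minimum by exhaustive enumeration.

    Returns ``(score, used, regular_exists)`` where ``used`` is the used
    edge set of the first optimal scenario in enumeration order and
    ``regular_exists`` says whether some optimal scenario is regular.
    """
    U = unfold(N)
    n = count_scenarios(G, U)
    if n > cap:
        raise CapExceeded(f"{n} scenarios exceed cap {cap}")
    best = math.inf
    best_used = None
    regular = False
    for xi in scenarios(G, U):
        tr = _trace(G, U, xi)
        s = tr.score if cost == "DC" else scenario_dup_score(G, N, xi, U)
        if s < best:
            best = s
            best_used = tr.used
            regular = not tr.used.has_conflict(N)
        elif s == best and not regular:
            regular = not _trace(G, U, xi).used.has_conflict(N)
    return best, best_used, regular


# ---------------------------------------------------------------------------
# cubic DP cross-check
# ---------------------------------------------------------------------------


def dc_score_cubic(G: GeneTree, N: PhyloNetwork):
    """Cubic-time DP for the optimal DC score (tree-child networks).

    delta(g,s) for non-reticulation s is the separable minimum over
    placements t, u of g's children below s, with pi(s,t) counting the
    minimal number of type I/II edges between s and t.
    """
    is_ret = {v: N.is_reticulation(v) for v in N.children}
    child_of = N.children
    parent_of = {v: ps for v, ps in N.parents.items()}

    @lru_cache(maxsize=None)
    def pi(s: int, t: int) -> float:
        if s == t:
            return 0
        if t in child_of[s]:
            return 1  # type I, the first edge
        if is_ret[t]:
            return 1 + min(pi(s, p) for p in parent_of[t])
        if not parent_of[t]:
            return math.inf  # reached the root without meeting s
        (p,) = parent_of[t]
        if is_ret[p]:
            return pi(s, p)  # type IV
        sib = next(c for c in child_of[p] if c != t)
        if is_ret[sib]:
            return pi(s, p)  # type III (bypass)
        return 1 + pi(s, p)  # type II

    non_ret = [v for v in N.children if not is_ret[v]]
    desc: dict[int, list[int]] = {}
    for s in N.children:
        seen, stack = set(), [s]
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            stack.extend(child_of[x])
        desc[s] = [t for t in seen if not is_ret[t]]

    delta: dict[tuple[int, int], float] = {}
    for g in G.postorder():
        if G.is_leaf(g):
            for s in non_ret:
                delta[(g, s)] = 0 if (N.is_leaf(s) and N.label[s] == G.label[g]) else math.inf
        else:
            for s in non_ret:
                total = 0.0
                for c in G.children[g]:
                    total += min(
                        (delta[(c, t)] + pi(s, t) for t in desc[s]), default=math.inf
                    )
                delta[(g, s)] = total
    pi.cache_clear()
    best = min(delta[(G.root, s)] for s in non_ret)
    return best - G.num_edges() if best < math.inf else math.inf
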