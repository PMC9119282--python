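"""Exact optimal-displayed-tree (ODT) solvers.

The scenario DP (module ``dpcore``) lower-bounds the cost of the best tree
displayed by N; when the used reticulation edges it reports are free of
conflicts (no sibling pair), any perfect set containing them realizes the
bound and the problem is solved by a single DP call.  Otherwise a conflict
{e, e'} is resolved by branching: the displayed trees of N split disjointly
into those of the pruned networks N_e and N_e', so recursing on both and
taking the better side is exact, with at most 2^{r+1}-1 DP invocations.

Also here: a depth-limited variant of the same recursion producing sound
lower/upper bounds; a per-blob solver for level-k networks that resolves
each biconnected component independently bottom-up (2^{k_B} switchings per
blob); the naive baseline enumerating all 2^r displayed trees; and the
completion of a conflict-free used set into a perfect set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .displayed import DisplayedTree, display, perfect_sets, prune_edge
from .dpcore import dp_dc, dp_dup
from .netmodel import CapExceeded, GeneTree, PhyloNetwork, StructureError, decompose
from .oracle import UsedEdgeSet
from .reconcile import dc_cost, dc_up_cost, dup_cost

__all__ = ["ODTResult", "BoundsResult", "SolverStats", "solve_odt", "bounds", "solve_levelk", "naive_odt", "complete_perfect"]

INF = math.inf
Edge = tuple[int, int]


@dataclass
class SolverStats:
    dp_invocations: int = 0
    max_depth: int = 0
    conflicts_branched: int = 0
    trees_enumerated: int = 0


@dataclass
class ODTResult:
    cost: float
    tree: DisplayedTree  # an optimal displayed tree of the input network
    perfect_set: frozenset  # switching of the input network inducing it
    stats: SolverStats
    variant: str
    cost_name: str


@dataclass
class BoundsResult:
    lower: float
    upper: float
    exact: bool
    stats: SolverStats


def complete_perfect(net: PhyloNetwork, used: UsedEdgeSet | frozenset) -> frozenset:
    """Extend a conflict-free used set to a perfect set.

    Reticulations untouched by the set get the parent edge with the lower
    tail node id, deterministically.
    """
    edges = used.edges if isinstance(used, UsedEdgeSet) else frozenset(used)
    Y = set()
    for r in net.reticulations():
        ins = [(p, r) for p in sorted(net.parents[r])]
        present = [e for e in ins if e in edges]
        if len(present) > 1:
            raise StructureError(f"used set has a conflict at reticulation {r}")
        Y.add(present[0] if present else ins[0])
    return frozenset(Y)


def _dp(cost: str):
    if cost == "DC":
        return dp_dc
    if cost == "DUP":
        return dp_dup
    raise ValueError(f"unknown cost {cost!r}")


def _cost_fn(cost: str):
    return dc_cost if cost == "DC" else dup_cost


def _origin_inverse(net: PhyloNetwork) -> dict[Edge, Edge]:
    return {net.edge_origin[e]: e for e in net.reticulation_edges()}


def naive_odt(G: GeneTree, N: PhyloNetwork, cost: str = "DC", cap: int = 16) -> ODTResult:
    """Minimum cost over all displayed trees by exhaustive enumeration."""
    r = N.n_reticulations()
    if r > cap:
        raise CapExceeded(f"r={r} exceeds naive enumeration cap {cap}")
    fn = _cost_fn(cost)
    stats = SolverStats()
    best, best_dt = INF, None
    for Y in perfect_sets(N):
        dt = display(N, Y)
        stats.trees_enumerated += 1
        c = fn(G, dt.tree)
        if c < best:
            best, best_dt = c, dt
    return ODTResult(best, best_dt, best_dt.perfect_set, stats, "naive", cost)


def solve_odt(
    G: GeneTree,
    N: PhyloNetwork,
    cost: str = "DC",
    mode: str = "auto",
    hybrid_threshold: int = 0,
    tiebreak: str = "first",
) -> ODTResult:
    """Exact ODT by conflict-resolution recursion.

    ``hybrid_threshold`` > 0 switches to naive enumeration once the current
    network has at most that many reticulations (enumeration is competitive
    for small r).
    """
    dp = _dp(cost)
    stats = SolverStats()

    def rec(net: PhyloNetwork, depth: int):
        stats.max_depth = max(stats.max_depth, depth)
        if hybrid_threshold > 0 and net.n_reticulations() <= hybrid_threshold:
            sub = naive_odt(G, net, cost)
            stats.trees_enumerated += sub.stats.trees_enumerated
            Yo = frozenset(net.edge_origin[e] for e in sub.perfect_set)
            return sub.cost, Yo
        stats.dp_invocations += 1
        res = dp(G, net, mode, tiebreak=tiebreak)
        if res.score == INF:
            raise StructureError("gene tree has labels absent from the network")
        confl = res.used.conflicts(net)
        if not confl:
            Y = complete_perfect(net, res.used)
            return res.score, frozenset(net.edge_origin[e] for e in Y)
        stats.conflicts_branched += 1
        e1, e2 = confl[0]  # first conflict by reticulation node id
        best, best_Y = INF, None
        for eprune, ekeep in ((e1, e2), (e2, e1)):
            child = prune_edge(net, eprune)
            c, Yo = rec(child, depth + 1)
            Yo = Yo | {net.edge_origin[ekeep]}
            if c < best:
                best, best_Y = c, Yo
        return best, best_Y

    cost_val, Yo = rec(N, 0)
    inv = _origin_inverse(N)
    # pruning may cascade-delete a reticulation whose only child edge died
    # (relaxed networks); its switching choice cannot affect the displayed
    # tree, so complete the lifted set deterministically
    Y = complete_perfect(N, frozenset(inv[o] for o in Yo))
    dt = display(N, Y)
    return ODTResult(cost_val, dt, Y, stats, "conflict-resolution", cost)


def bounds(G: GeneTree, N: PhyloNetwork, maxdepth: float = INF, cost: str = "DC", mode: str = "auto") -> BoundsResult:
    """Sound lower/upper bounds on the ODT cost by depth-limited recursion.

    At a cutoff with a conflicted usage set, the DP score is the lower
    bound; the upper bound is the cost of the displayed tree obtained by
    deterministically resolving every conflict (keep the lower-node-id edge
    of each conflicted pair) and completing to a perfect set.  Interval
    endpoints combine by minimum across the two branches; unlimited depth
    gives the exact cost.
    """
    dp = _dp(cost)
    fn = _cost_fn(cost)
    stats = SolverStats()

    def rec(net: PhyloNetwork, depth: int):
        stats.max_depth = max(stats.max_depth, depth)
        stats.dp_invocations += 1
        res = dp(G, net, mode)
        if res.score == INF:
            raise StructureError("gene tree has labels absent from the network")
        confl = res.used.conflicts(net)
        if not confl:
            return res.score, res.score
        if depth >= maxdepth:
            drop = {pair[1] for pair in confl}  # higher edge of each sibling pair
            resolved = UsedEdgeSet(
                direct=res.used.direct - drop, potential=res.used.potential - drop
            )
            Y = complete_perfect(net, resolved)
            upper = fn(G, display(net, Y).tree)
            return res.score, upper
        e1, e2 = confl[0]
        l = u = INF
        for e in (e1, e2):
            l2, u2 = rec(prune_edge(net, e), depth + 1)
            l, u = min(l, l2), min(u, u2)
        return l, u

    l, u = rec(N, 0)
    return BoundsResult(l, u, l == u, stats)


# ---------------------------------------------------------------------------
# level-k per-blob solver
# ---------------------------------------------------------------------------


def _forest_roots(G: GeneTree, labels: set[str]) -> list[int]:
    """Roots of the maximal subtrees of G whose leaf labels all lie in ``labels``."""
    inside: dict[int, bool] = {}
    for g in G.postorder():
        if G.is_leaf(g):
            inside[g] = G.label[g] in labels
        else:
            inside[g] = all(inside[c] for c in G.children[g])
    roots = []
    for g in G.postorder():
        if inside[g] and (g == G.root or not inside[G.parent[g]]):
            roots.append(g)
    return roots


def solve_levelk(G: GeneTree, N: PhyloNetwork, cost: str = "DC", mode: str = "auto") -> ODTResult:
    """Exact ODT-DC resolving each blob independently, bottom-up.

    For a non-root blob B the embedding of every maximal gene subtree whose
    labels fall under B's root is confined to the subnetwork there, and the
    entry edge is charged the path from the subnetwork root down to the
    subtree root's image; so B's switching is chosen by minimizing the sum
    of DC-up costs of those subtrees against each candidate resolved
    subtree (2^{k_B} candidates).  A gene subtree without a parent edge
    (the whole gene tree) contributes its plain DC cost instead.  The blob
    containing N's root, if any, is resolved last against the full DC
    objective.  The assembled switching's displayed tree and cost are
    returned; the result always agrees with :func:`solve_odt`.
    """
    if cost != "DC":
        raise ValueError("the per-blob solver supports the DC cost only")
    missing = set(G.leaf_labels()) - N.labels()
    if missing:
        raise StructureError(f"gene tree has labels absent from the network: {sorted(missing)}")
    stats = SolverStats()
    dec = decompose(N)

    depth = {N.root: 0}
    for v in N.topological_order():
        for c in N.children[v]:
            depth[c] = min(depth.get(c, 1 << 30), depth[v] + 1)
    order = sorted(range(len(dec.blobs)), key=lambda i: -depth[dec.blobs[i].root])

    cur = N
    chosen: set[Edge] = set()
    for bi in order:
        blob = dec.blobs[bi]
        v = blob.root
        is_root_blob = v == N.root
        sub = cur if is_root_blob else cur.subnetwork(v)
        labels = sub.labels()
        froots = _forest_roots(G, labels)
        subtrees = [G.subtree(t) for t in froots]
        best, best_Y = INF, None
        for Y in perfect_sets(sub):
            stats.dp_invocations += 1
            T = display(sub, Y).tree
            if is_root_blob:
                obj = dc_cost(G, T)
            else:
                obj = 0
                for t, gt in zip(froots, subtrees):
                    obj += dc_cost(G, T) if t == G.root else dc_up_cost(gt, T)
                    # note: t == G.root means the whole gene tree embeds here
                    # and has no entry edge to charge
            if obj < best:
                best, best_Y = obj, Y
        chosen.update(sub.edge_origin[e] for e in best_Y)
        # prune the non-chosen edge of every reticulation of this blob
        to_prune = [
            sub.edge_origin[e]
            for r in sub.reticulations()
            for e in ((p, r) for p in sub.parents[r])
            if e not in best_Y
        ]
        for o in to_prune:
            inv = _origin_inverse(cur)
            if o in inv:  # a cascade may already have removed the edge
                cur = prune_edge(cur, inv[o])

    inv = _origin_inverse(N)
    Y = complete_perfect(N, frozenset(inv[o] for o in chosen if o in inv))
    dt = display(N, Y)
    return ODTResult(_cost_fn(cost)(G, dt.tree), dt, Y, stats, "level-k", cost)
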