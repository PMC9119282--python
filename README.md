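# netrecon

Reconciliation of gene trees with rooted binary **phylogenetic networks**
under the deep-coalescence (DC) and duplication (DUP) parsimony costs, with
exact solvers for the **optimal displayed tree** (ODT) problem.

## The problem

A phylogenetic network N is a rooted binary DAG whose leaves are labeled
one-to-one with species; *reticulation* nodes (indegree 2) model
hybridization, recombination, or horizontal transfer. Keeping exactly one
incoming edge per reticulation (a *switching*, or perfect set Y) and
contracting degree-restricted nodes yields one of the up to 2^r *displayed
trees* N_Y of the network. Given a gene tree G (leaf labels may repeat —
MUL-trees are allowed), the ODT problem asks for the displayed tree
minimizing a reconciliation cost:

- **deep coalescence**: `DC(G,S) = Σ_{⟨v,w⟩∈E(G)} (‖M(v),M(w)‖ − 1)`,
  the number of extra gene lineages under the lca-mapping M;
- **duplication**: `DUP(G,S) = Σ_{g∈T(G)} [M(g) = M(g') or M(g) = M(g'')]`,
  the number of gene nodes mapping onto a child's image.

Enumerating all 2^r displayed trees is hopeless for reticulation-rich
networks. `netrecon` instead embeds G directly into the network: a dynamic
program over V(G) × V(N) computes, in O(|G||N|) time, the minimal
*scenario score* — a provable lower bound on the ODT cost — together with
the set of reticulation edges the optimal embedding uses. When that set
contains no *conflict* (both edges of one reticulation), the bound is
tight and the displayed tree is read off directly. Otherwise the solver
branches on the conflicting pair, pruning one edge at a time: at most
2^{r+1} − 1 DP calls in the worst case, but near-linear work in practice
when gene tree and network are congruent. The approach is exact on
*tree-child* networks (every non-leaf node has a non-reticulation child)
and on the broader *relaxed* class (no node has two reticulation
children); depth-limited recursion yields sound lower/upper bounds, and a
per-blob variant handles level-k networks component by component.

## Worked example

The network `((a,(b)#H1)u,(#H1,c)v)r;` (extended Newick; `#H1` is a
reticulation with parents u and v) displays the two trees `((a,b),c)` and
`(a,(b,c))`. For the gene tree `(a,c);`:

```sh
$ netrecon solve gene.nwk network.enwk --cost dc
```

```json
"results": {
  "cost": 1,
  "perfect_set": [["v", "#H1"]],
  "tree": "(a,(b,c));",
  "variant": "conflict-resolution"
},
"stats": {"conflicts_branched": 1, "dp_invocations": 3, "max_depth": 1}
```

Both displayed trees cost 1 extra lineage, so the optimum is 1 — yet the
scenario DP alone reports a score of 0 with a conflict:

```sh
$ netrecon score gene.nwk network.enwk --cost dc
```

```json
"results": {
  "score": 0,
  "used_edges": {"direct": [], "potential": [["u", "#H1"], ["v", "#H1"]]},
  "conflicts": [[["u", "#H1"], ["v", "#H1"]]]
}
```

The lone scenario for this pair bypasses both reticulation edges, using
each "potentially": no single displayed tree realizes the score-0
embedding, which is exactly why the solver branched once (3 DP calls)
before certifying cost 1. Other verbs: `bounds` (depth-limited l/u
interval), `levelk` (per-blob solver), `naive` (exhaustive baseline),
`validate` (network classification), `simulate` (random gene-tree/network
pairs in three congruence regimes).

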