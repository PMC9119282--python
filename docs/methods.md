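# Methods

## Model and definitions

A **phylogenetic network** N is a rooted binary DAG on a species set X:
leaves (indegree 1, outdegree 0) are labeled one-to-one with X, *tree
nodes* have indegree ≤ 1 and outdegree 2, *reticulations* have indegree 2
and outdegree 1. A **gene tree** G is a rooted binary tree whose leaves
carry species labels, possibly with repeats (MUL-tree); its labels need
not cover X. Two classes matter:

- **tree-child** — every non-leaf node has at least one non-reticulation
  child;
- **relaxed** — every node has at most one reticulation child. This
  strictly contains tree-child (a reticulation's child may itself be a
  reticulation). Binary networks outside the relaxed class (a tree node
  with two reticulation children) are rejected: the dynamic program below
  is provably incorrect there, because an optimal displayed tree may
  delete a tree node entirely while the DP still charges its edges.

A **perfect set** (switching) Y keeps one incoming edge per reticulation;
deleting the others and contracting indegree-1/outdegree-1 nodes, dead
unlabeled leaves, and a unary root yields the displayed tree N_Y. The
contraction is implemented as a three-rule rewriting system run to a fixed
point; tests assert confluence under randomized rule order rather than
assuming it. Deleting dead unlabeled leaves is a no-op on tree-child
networks but required for relaxed ones (a reticulation can lose its only
child edge).

**Costs between trees.** With the lca-mapping M (leaves to same-label
leaves, internal nodes to the lca of the children's images):
`DC(G,S) = Σ_edges (‖M(v),M(w)‖ − 1)` counts extra gene lineages;
`DUP(G,S)` counts internal gene nodes with `M(g) ∈ {M(g'), M(g'')}`.
`DCup(G,S) = DC(G,S) + ‖M(G.root), S.root‖` additionally charges the path
from the species root down to the gene root's image; it is the per-tree
objective of the level-k solver. Path lengths are defined for comparable
nodes only; an incomparable query is a programming error, which the
monotone M rules out.

## Scenarios and the unfolded network

Embedding G into N directly goes through the **unfolded network** N̂:
processing reticulations bottom-up, each reticulation's subtree is copied,
detached from one parent and re-attached as a copy, until a (semi-binary)
tree remains whose root-leaf paths biject with those of N; the origin map
σ sends copies back to N. A **scenario** ξ assigns each gene leaf a
same-label leaf of N̂; its lca-extension M_ξ maps every gene node to a
leaf or tree node of N̂. Each N̂-edge visited by a gene edge has one of
four types — I (first edge), II (sibling of the bottom node is not a
reticulation in origin), III (it is: the visited path *bypasses* that
reticulation edge), IV (top node has outdegree 1) — and the DC *score* of
ξ counts types I/II, minus one per gene edge. The DUP score counts gene
nodes sharing their M_ξ image with a child.

A reticulation edge is **directly used** when a type-I/II edge maps onto
it and **potentially used** when its sibling is bypassed; the used set
Υ_ξ has a **conflict** if it contains both edges of one reticulation, and
ξ is **regular** otherwise. The bridge to displayed trees: every perfect
set Y induces a scenario ξ_Y (each leaf maps to its unique surviving
copy), `DC(G, N_Y) ≥ score(ξ_Y)` always, and the optimal scenario score is
a lower bound on the ODT cost, tight exactly when an optimal regular
scenario exists.

One caveat discovered during validation: the classical "equality iff ξ_Y
is regular" characterization silently assumes the gene tree's labels cover
the network's. When labels are missing, ξ_Y can bypass an edge *of Y*
whose sibling is never directly used, remaining regular while the bound is
strict. The tests therefore assert the full equivalence on label-covering
gene trees and only the bound plus the "equality ⇒ regular" direction for
subset-label inputs. None of the solvers relies on the failing direction.

## The efficient dynamic program

Three tables over V(G) × V(N) (two for DUP), filled with G in postorder
and N children-before-parents; every cell is O(1), giving O(|G||N|) time
and ≤ 3|G||N| cells:

- `δ(g,s)` — minimal type-I/II count embedding G|g with g's image fixed
  at s (s never a reticulation);
- `δf(g,s)` — δ plus the cost of g's incoming edge entering at tree node
  s ("first-edge" table, kept explicit for testability);
- `δ↑(g,s)` — g's image anywhere at or below s.

With τ(s) = 0 for reticulations and 1 otherwise: δ of an internal pair is
`δf(g',s) + δf(g'',s)`; leaf cases are 0 on label agreement (a species
leaf under a label-uniform gene subtree also costs 0) and +∞ otherwise;
`δf(g,s) = min(δ(g,s), min_c τ(c) + δ↑(g,c))`;
`δ↑(g,s) = min(δ(g,s), min_c τ(s')τ(s'') + δ↑(g,c))` at tree nodes,
`τ(s') + δ↑(g,s')` at a reticulation, δ at leaves. The optimal score is
`−|E(G)| + min_s δ(G.root, s)`. On tree-child inputs the reticulation case
always adds 1 (its child is never a reticulation), so the single τ-form
covers both classes and reduces to the tree-child rule exactly.

The DUP program uses δ and δ↑ only: an internal pair takes the best of two
duplication branches (`1 + δ(child₁,s) + δ↑(child₂,s)` and the mirror) and
two speciation branches (`δ↑(child₁,s') + δ↑(child₂,s'')` and the mirror);
a species leaf under a label-uniform gene subtree costs |L(G|g)| − 1
(every internal node duplicates); δ↑ descends freely. A gene label absent
from the network makes every root cell +∞; the DP reports an infinite
score with an empty used set, and the solvers refuse such inputs
explicitly.

**Usage backtracking.** Descending through a reticulation edge adds it as
directly used (ρ); taking the branch that bypasses a reticulation child
adds the bypassed edge's sibling as potentially used (ρ̄, DC only — the
printed DUP rules track direct use only). In the relaxed class the
reticulation pass-down rule additionally records
reticulation-to-reticulation descent edges: by the type classification
these are always type IV and never "directly used", but the switching
realizing the scenario must contain them, so Υ deliberately extends the
literal definition there.

Two refinements make the backtracked set trustworthy:

1. *Realizability.* The δ-recurrence relaxes the constraint that the two
   children's images have their lca exactly at s — both may descend
   through the same child of s. Such combinations undershoot their
   constrained semantics; they never win the root optimum, but value-tied
   backtracking could walk into them and emit a usage set belonging to no
   optimal scenario. Each cell therefore carries a realizability bit
   (computed in the same sweep), and backtracking prefers realizable
   branches, realizable first-edge *pairs* (not both children strictly
   through the same network child), and a realizable argmin cell. With
   this, the reported set equals Υ of an actual optimal scenario —
   verified by exhaustive enumeration on tree-child instances.
2. *Tie-break.* Among equal-score branches the default prefers descending
   before stopping (children in node-id order): placing gene nodes as low
   as possible tracks the lca-embedding of a displayed tree, which keeps
   the backtracked scenario regular on congruent inputs — measured on
   displayed-tree gene trees, the solver then branches on < 10% of
   instances versus ~100% under the stop-first order. An opt-in
   `tiebreak="min-usage"` instead greedily minimizes each cell's usage set
   lexicographically (same score, deterministic; per-cell greediness does
   not guarantee a globally minimal set).

## Solvers

**Conflict resolution** (`solve_odt`). Run the DP; a conflict-free used
set completes to a perfect set (untouched reticulations take the
lower-tail-id edge) whose displayed tree realizes the score. Otherwise the
first conflict (by reticulation node id) is resolved by recursing on the
two networks obtained by pruning one conflict edge each — the displayed
trees of N partition (as a multiset over switchings) into those of the two
pruned networks, so taking the better branch is exact, with ≤ 2^{r+1} − 1
DP invocations. Pruned networks carry an edge-origin map so the winning
switching is expressed in the input network's edges; a pruning cascade in
relaxed networks can delete a reticulation outright (its only child edge
dies), in which case its choice cannot affect the tree and the lifted set
is completed deterministically. An optional hybrid threshold switches to
exhaustive enumeration once r is small, where enumeration is competitive.
Results report DP invocations, recursion depth, and conflicts branched.
Note the *topology sets* of the two branches need not be disjoint —
distinct switchings can induce the same tree (a one-reticulation bubble
already shows this); only the switching-indexed partition holds, and it is
all the recursion needs.

**Bounds** (`bounds`). The same recursion cut off at a depth limit: a
cutoff node contributes its DP score as lower bound and, as upper bound,
the cost of the displayed tree obtained by deterministically resolving
every conflict (keep the lower-node-id edge of each conflicted pair) and
completing; siblings combine by minimum on both endpoints. Intervals are
sound at every depth, nest as the depth grows, and collapse to the exact
cost at unlimited depth — the cutoff upper bound is always finite, which
keeps shallow runs informative.

**Level-k per-blob solver** (`solve_levelk`, DC only). Nontrivial
biconnected components (blobs) of the underlying undirected graph are
node-disjoint, each hanging below a cut edge, and both endpoints of every
reticulation edge lie in one blob. Which blob region each gene node's
image falls in is switching-invariant, so the total DC cost decouples by
blob. Blobs are resolved bottom-up: for a non-root blob, every maximal
gene subtree whose labels fall under the blob root must embed in the
subnetwork there, and its entry edge is charged the path from the
subnetwork root to the subtree root's image — so the blob's switching is
chosen by minimizing the summed DCup of those subtrees over its 2^{k_B}
candidate resolutions (already-resolved lower blobs contribute constants,
which cannot change the argmin). A parentless subtree (the whole gene tree
fits under the blob root) contributes plain DC — it has no entry edge, and
charging one can misdirect the choice. The blob containing the network
root, if any, is resolved last against the full DC objective; the
assembled switching's tree and cost are recomputed on the input network.
Total work O(2^k |G||N|) for level-k networks, and the result always
equals `solve_odt`'s (asserted across all test sweeps).

**Naive baseline** (`naive_odt`). All 2^r switchings displayed and scored
(default cap r ≤ 16); the first optimum in enumeration order is the
deterministic witness. It anchors every exactness test.

## Oracles

Two independent ground-truth routes pin the DP down at small scale:
exhaustive scenario enumeration over the unfolded network (caps: r ≤ 8 for
unfolding, 10^6 scenarios), and a cubic-time DP over node pairs whose path
helper π(s,t) counts the minimal type-I/II edges between comparable nodes
(tree-child only; its case analysis follows the edge types, with the
reticulation case branching over both parents). The efficient DP is
required to agree with both on every instance of a 300-instance seeded
sweep plus all fixtures, and the DUP program with brute force likewise —
zero tolerated mismatches.

## Random instance generation

`simgen` emulates the standard random benchmark designs:

- **Species trees**: Yule pure-birth (uniform lineage splits, Exp(1/k)
  waiting times), height normalized to 1. Only relative node times matter
  downstream, since reticulation insertion draws subdivision times
  uniformly within an edge's interval; absolute birth-death time scales
  would cancel.
- **Reticulations**: the time-consistent rejection scheme — subdivide two
  distinct non-reticulation edges, draw each new vertex's time uniformly
  within its edge, add an edge from the earlier to the later vertex
  (guaranteeing acyclicity), and undo if the requested class (tree-child
  or relaxed) is violated; 1000·k attempts before giving up. Leaf times
  are untouched, so displayed trees remain ultrametric.
- **Gene trees**: Yule–Harding (split a uniformly chosen leaf; labels by
  random permutation).
- **Dataset styles**: R1 — independent gene tree on all n labels; R2 — on
  a uniform-size random label subset (2..n); R3 — a uniformly sampled
  displayed tree of the network. R3 pairs embed with DC cost 0 by
  construction and are the congruent regime where conflict resolution
  rarely branches.

What the generator does *not* emulate: sequence evolution and gene-tree
estimation error, incomplete lineage sorting within branches, and
duplication-loss gene family dynamics. Passing tests therefore certify the
combinatorial machinery — costs, bounds, exactness, scaling in the number
of reticulations — not robustness to phylogenetic reconstruction error in
real pipelines.

All randomness flows through explicit integer seeds (NumPy Generators);
per-instance streams are derived as `default_rng([seed, index])`, so every
dataset and test sweep is reproducible byte-for-byte.

## Problem sizes and numerical choices

Test sweeps use networks of 4–12 leaves with 1–8 reticulations — small
enough for the exponential oracles (scenario enumeration is capped at a
few thousand scenarios per instance; displayed-tree enumeration at 2^r
with r ≤ 8) yet large enough to exercise multi-blob structure, relaxed
chains, and conflict branching; the scaling study uses 50 instances per
reticulation count on 12-leaf networks. The DP itself handles much larger
inputs (hundreds of leaves, dozens of reticulations, in under a second).
Infinite table entries are `math.inf`, never a large finite sentinel, so
min/addition semantics are exact; all finite scores are integers.
Canonical serialization (children ordered by smallest descendant leaf
label, hybrid subtrees at first occurrence, tags renumbered in print
order) makes isomorphism checking a string comparison, and all argmins and
tie-breaks are fixed deterministically (node-id order, first-in-stream),
so repeated runs produce identical reports.

## Known limitations

- Exactness is limited to relaxed networks; general binary networks are
  rejected rather than answered approximately.
- The DUP usage rules track no bypass information, and the per-blob solver
  covers the DC cost only, both mirroring the algorithmic theory; DUP on
  level-k networks falls back to plain conflict resolution.
- Unrooted gene trees, duplication-loss cost, and branch lengths on parsed
  inputs are out of scope.
- `min-usage` is a per-cell greedy heuristic: it cannot promise the
  globally smallest conflicted set, only determinism at no cost in score.
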