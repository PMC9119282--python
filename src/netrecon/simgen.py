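"""Random instance generation.

Species trees come from a Yule pure-birth process with the height
normalized to 1 (only relative node times matter downstream: reticulation
insertion draws subdivision times uniformly between the endpoints of an
edge).  Reticulations are inserted by the standard time-consistent
rejection scheme: subdivide two distinct non-reticulation edges, draw a
time for each new vertex uniformly within its edge's time interval, and
add an edge from the lower-time vertex to the higher-time vertex; if the
result leaves the requested class (tree-child or relaxed), undo and retry.
Gene trees follow the Yule-Harding model (repeatedly split a uniformly
chosen leaf; labels by random permutation).

Dataset styles mirror the three random-benchmark designs:

  R1  gene tree on all n network labels, drawn independently;
  R2  gene tree on a uniform-size random subset of the labels;
  R3  gene tree is a uniformly drawn displayed tree of the network
      (topologically congruent pairs -- the solver rarely branches).
"""

from __future__ import annotations

import hashlib
import json
import pathlib
from dataclasses import dataclass

import numpy as np

from .displayed import display
from .netmodel import GeneTree, PhyloNetwork, StructureError, serialize, validate

__all__ = [
    "TimedTree",
    "sim_species_tree",
    "add_reticulations",
    "sim_gene_tree",
    "sample_displayed",
    "make_dataset",
    "write_dataset",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class TimedTree:
    """Ultrametric species tree: root at time 0, all leaves at time 1."""

    children: dict[int, tuple[int, ...]]
    label: dict[int, str]
    root: int
    time: dict[int, float]

    def as_gene_tree(self) -> GeneTree:
        return GeneTree(dict(self.children), dict(self.label), self.root)

    def as_network(self) -> PhyloNetwork:
        net = PhyloNetwork(dict(self.children), dict(self.label), self.root)
        net.node_time = dict(self.time)
        return net


def sim_species_tree(n: int, seed) -> TimedTree:
    """Yule tree on n leaves with labels x1..xn, height normalized to 1."""
    if n < 2:
        raise ValueError("need at least 2 leaves")
    rng = _rng(seed)
    # the root is the first split, at time 0
    children: dict[int, tuple[int, ...]] = {0: (1, 2), 1: (), 2: ()}
    time = {0: 0.0}
    active = [1, 2]
    counter = 3
    t = 0.0
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / k)
        i = int(rng.integers(k))
        v = active[i]
        a, b = counter, counter + 1
        counter += 2
        children[v] = (a, b)
        children[a] = ()
        children[b] = ()
        time[v] = t
        active[i] = a
        active.append(b)
    t_end = t + rng.exponential(1.0 / n)
    labels = [f"x{i + 1}" for i in range(n)]
    perm = rng.permutation(n)
    label = {}
    for j, v in enumerate(active):
        time[v] = t_end
        label[v] = labels[perm[j]]
    scale = t_end if t_end > 0 else 1.0
    time = {v: tv / scale for v, tv in time.items()}
    return TimedTree(children=children, label=label, root=0, time=time)


def add_reticulations(S: TimedTree, k: int, seed, network_class: str = "tree-child") -> PhyloNetwork:
    """Insert k time-consistent reticulations by rejection sampling.

    Raises ``StructureError`` when the rejection budget (1000*k attempts)
    is exhausted.  The returned network carries ``node_time``.
    """
    rng = _rng(seed)
    children = {v: list(cs) for v, cs in S.children.items()}
    parents: dict[int, list[int]] = {v: [] for v in children}
    for v, cs in children.items():
        for c in cs:
            parents[c].append(v)
    label = dict(S.label)
    time = dict(S.time)
    counter = max(children) + 1

    def build() -> PhyloNetwork:
        net = PhyloNetwork({v: tuple(cs) for v, cs in children.items()}, label, S.root)
        net.node_time = dict(time)
        return net

    def class_ok(net: PhyloNetwork) -> bool:
        rep = validate(net)
        if network_class == "tree-child":
            return rep.is_tree_child
        if network_class == "relaxed":
            return rep.is_relaxed
        raise ValueError(f"unknown network class {network_class!r}")

    def subdivide(edge):
        nonlocal counter
        p, c = edge
        x = counter
        counter += 1
        children[p][children[p].index(c)] = x
        children[x] = [c]
        parents[c][parents[c].index(p)] = x
        parents[x] = [p]
        time[x] = rng.uniform(time[p], time[c])
        return x

    def undo(x):
        (p,) = parents[x]
        (c,) = children[x]
        children[p][children[p].index(x)] = c
        parents[c][parents[c].index(x)] = p
        del children[x], parents[x], time[x]

    added = 0
    budget = max(1, 1000 * k)
    attempts = 0
    while added < k:
        attempts += 1
        if attempts > budget:
            raise StructureError(f"reticulation insertion budget exhausted ({budget} attempts)")
        edges = [
            (p, c)
            for p, cs in children.items()
            for c in cs
            if len(parents[c]) == 1  # non-reticulation edges only
        ]
        i, j = rng.choice(len(edges), size=2, replace=False)
        x = subdivide(edges[i])
        y = subdivide(edges[j])
        if time[x] == time[y]:
            undo(y)
            undo(x)
            continue
        tail, head = (x, y) if time[x] < time[y] else (y, x)
        children[tail].append(head)
        parents[head].append(tail)
        if class_ok(build()):
            added += 1
        else:
            children[tail].remove(head)
            parents[head].remove(tail)
            undo(y)
            undo(x)
    return build()


def sim_gene_tree(labels, seed) -> GeneTree:
    """Yule-Harding random topology over the given label set."""
    labels = sorted(labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")
    rng = _rng(seed)
    perm = [labels[int(i)] for i in rng.permutation(len(labels))]
    children: dict[int, tuple[int, ...]] = {0: (1, 2), 1: (), 2: ()}
    label = {1: perm[0], 2: perm[1]}
    leaves = [1, 2]
    counter = 3
    for lbl in perm[2:]:
        i = int(rng.integers(len(leaves)))
        v = leaves[i]
        a, b = counter, counter + 1
        counter += 2
        children[v] = (a, b)
        children[a] = ()
        children[b] = ()
        label[a] = label.pop(v)
        label[b] = lbl
        leaves[i] = a
        leaves.append(b)
    return GeneTree(children, label, 0)


def sample_displayed(N: PhyloNetwork, seed) -> GeneTree:
    """A uniformly random displayed tree of N (uniform over perfect sets)."""
    rng = _rng(seed)
    Y = set()
    for r in N.reticulations():
        ps = sorted(N.parents[r])
        Y.add((ps[int(rng.integers(len(ps)))], r))
    return display(N, frozenset(Y)).tree


def make_dataset(style: str, n: int, r: int, count: int, seed: int, network_class: str = "tree-child"):
    """``count`` seeded (GeneTree, PhyloNetwork) pairs in the given style."""
    if style not in ("R1", "R2", "R3"):
        raise ValueError(f"unknown dataset style {style!r}")
    pairs = []
    for i in range(count):
        rng = np.random.default_rng([seed, i])
        S = sim_species_tree(n, rng)
        N = add_reticulations(S, r, rng, network_class)
        labels = sorted(N.labels())
        if style == "R1":
            G = sim_gene_tree(labels, rng)
        elif style == "R2":
            m = int(rng.integers(2, n + 1))
            subset = [labels[int(j)] for j in rng.choice(n, size=m, replace=False)]
            G = sim_gene_tree(subset, rng)
        else:
            G = sample_displayed(N, rng)
        pairs.append((G, N))
    return pairs


def write_dataset(pairs, outdir, style: str, n: int, r: int, seed: int) -> dict:
    """Write paired ``<stem>.gtree.nwk`` / ``<stem>.net.enwk`` files + manifest."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, (G, N) in enumerate(pairs):
        stem = f"{style.lower()}_n{n}_r{r}_{i:03d}"
        gpath = outdir / f"{stem}.gtree.nwk"
        npath = outdir / f"{stem}.net.enwk"
        gtxt, ntxt = serialize(G), serialize(N)
        gpath.write_text(gtxt + "\n")
        npath.write_text(ntxt + "\n")
        entries.append(
            {
                "stem": stem,
                "gene_tree": gpath.name,
                "network": npath.name,
                "gene_sha256": hashlib.sha256(gtxt.encode()).hexdigest(),
                "net_sha256": hashlib.sha256(ntxt.encode()).hexdigest(),
            }
        )
    manifest = {
        "schema": 1,
        "style": style,
        "n": n,
        "r": r,
        "count": len(pairs),
        "seed": seed,
        "files": entries,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
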