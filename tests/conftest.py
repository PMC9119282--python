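"""Shared fixtures: the worked-example trees/networks and seeded instance streams."""

import numpy as np
import pytest

import netrecon as nr
from netrecon.oracle import count_scenarios, unfold

F1_TEXT = "((a,(b)#H1)u,(#H1,c)v)r;"
F3_TEXT = "(((a,(b)#H1),(#H1,c)),((d,(e)#H2),(#H2,f)));"
F4_TEXT = "((a,((b)#H2)#H1)u,(#H1,(#H2,c)w)v)r;"
F2A_TEXT = "((a,(b,c)),d);"
F2B_TEXT = "(a,d);"
F2S_TEXT = "((a,(b,c)),d);"
F5_TEXT = "((a,b),(b,c));"


@pytest.fixture
def F1():
    """Tree-child, one reticulation (parents u,v; child b)."""
    return nr.parse_enewick(F1_TEXT)


@pytest.fixture
def F3():
    """Level-1, two independent blobs, r=2."""
    return nr.parse_enewick(F3_TEXT)


@pytest.fixture
def F4():
    """Relaxed but not tree-child: H1's only child is reticulation H2."""
    return nr.parse_enewick(F4_TEXT)


@pytest.fixture
def F2a():
    return nr.parse_gene_tree(F2A_TEXT)


@pytest.fixture
def F2b():
    return nr.parse_gene_tree(F2B_TEXT)


@pytest.fixture
def F2s():
    """Species tree of the running example, as a tree."""
    return nr.parse_gene_tree(F2S_TEXT)


@pytest.fixture
def F2s_net():
    """Same species tree as a 0-reticulation network."""
    return nr.parse_enewick(F2S_TEXT)


@pytest.fixture
def F5():
    """MUL gene tree with two copies of b."""
    return nr.parse_gene_tree(F5_TEXT)


def canon(obj_or_text) -> str:
    """Canonical newick of a tree/network or (e)newick string."""
    if isinstance(obj_or_text, str):
        try:
            obj_or_text = nr.parse_enewick(obj_or_text)
        except nr.ParseError:
            obj_or_text = nr.parse_gene_tree(obj_or_text)
    return nr.serialize(obj_or_text)


def ret_edges(net):
    """Reticulation edges sorted by (tail id, head id); for F1 this is
    [(u,H1), (v,H1)] since u is printed before v."""
    return net.reticulation_edges()


def instance_stream(
    seed,
    count,
    n_range=(4, 9),
    r_range=(1, 5),
    classes=("tree-child", "tree-child", "tree-child", "relaxed"),
    style_cycle=("R1", "R2", "R3"),
    scenario_cap=None,
):
    """Yield ``count`` seeded (GeneTree, PhyloNetwork) pairs.

    Instances violating ``scenario_cap`` (total scenario count of the
    unfolded network) are skipped so brute-force oracles stay feasible;
    the stream is a deterministic function of ``seed``.
    """
    produced = 0
    i = 0
    while produced < count:
        rng = np.random.default_rng([seed, i])
        i += 1
        n = int(rng.integers(*n_range))
        r = int(rng.integers(*r_range))
        klass = classes[i % len(classes)]
        try:
            S = nr.sim_species_tree(n, rng)
            N = nr.add_reticulations(S, r, rng, klass)
        except nr.StructureError:
            continue
        style = style_cycle[i % len(style_cycle)]
        labels = sorted(N.labels())
        if style == "R1":
            G = nr.sim_gene_tree(labels, rng)
        elif style == "R2":
            m = int(rng.integers(2, n + 1))
            subset = [labels[int(j)] for j in rng.choice(n, size=m, replace=False)]
            G = nr.sim_gene_tree(subset, rng)
        else:
            G = nr.sample_displayed(N, rng)
        if scenario_cap is not None and count_scenarios(G, unfold(N, cap=16)) > scenario_cap:
            continue
        produced += 1
        yield G, N
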