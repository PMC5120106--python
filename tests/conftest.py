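"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's own algorithms: parsimony
scores are checked against exhaustive enumeration of ancestral labelings
(and, for tree search, of all unrooted topologies built by edge insertion).
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import albomito as am
from albomito.haplotree import HaplogroupTree, Node, SitePattern


@pytest.fixture(scope="session")
def tree() -> HaplogroupTree:
    return am.HaplogroupTree.load_fixture()


@pytest.fixture(scope="session")
def panel(tree):
    return am.derive_marker_panel(tree)


@pytest.fixture(scope="session")
def genomes(tree):
    return am.simulate_along_tree(tree, seed=11)


@pytest.fixture(scope="session")
def reference(tree, genomes) -> str:
    return genomes.node_seqs[tree.reference_leaf]


@pytest.fixture(scope="session")
def table1():
    return am.load_fixture_table("table1")


@pytest.fixture(scope="session")
def table2():
    return am.load_fixture_table("table2")


# --------------------------------------------------------------------------
# Oracles
# --------------------------------------------------------------------------


def random_multifurcating_tree(rng, taxa) -> HaplogroupTree:
    nodes = [Node(t) for t in taxa]
    while len(nodes) > 1:
        k = 2 if len(nodes) == 2 else int(rng.integers(2, min(3, len(nodes)) + 1))
        parent = Node()
        for _ in range(k):
            parent.add_child(nodes.pop(int(rng.integers(len(nodes)))))
        nodes.append(parent)
    return HaplogroupTree(nodes[0])


def brute_site_score(tree: HaplogroupTree, pat: SitePattern) -> int:
    """Minimum changes for one site by enumerating all internal labelings."""
    internals = [n for n in tree.preorder() if not n.is_leaf]
    best = None
    for combo in itertools.product("ACGT", repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, combo)}
        cost = 0
        for n in tree.preorder():
            if n.parent is None:
                continue
            up = assign[id(n.parent)]
            down = assign.get(id(n)) or pat.states.get(n.name)
            if down is None:
                continue
            cost += up != down
        best = cost if best is None else min(best, cost)
    return best


def enumerate_unrooted_edge_lists(n_taxa: int):
    """All unrooted binary topologies on leaves 0..n-1 as edge lists,
    built by inserting each leaf on every existing edge."""
    base = [(0, n_taxa), (1, n_taxa), (2, n_taxa)]
    tops = [(base, n_taxa + 1)]
    for leaf in range(3, n_taxa):
        nxt = []
        for edges, next_id in tops:
            for i, (u, v) in enumerate(edges):
                new = edges[:i] + edges[i + 1:]
                new += [(u, next_id), (next_id, v), (leaf, next_id)]
                nxt.append((new, next_id + 1))
        tops = nxt
    return [edges for edges, _ in tops]


def brute_best_parsimony(patterns, n_taxa: int, taxa_names) -> int:
    """Minimum parsimony score over all topologies and ancestral labelings
    (vectorised enumeration; independent of the library's tree search)."""
    name_of = dict(enumerate(taxa_names))
    best_overall = None
    n_internal = n_taxa - 2
    labelings = np.array(
        list(itertools.product(range(4), repeat=n_internal)), dtype=np.int8)
    base_code = {b: i for i, b in enumerate("ACGT")}
    for edges in enumerate_unrooted_edge_lists(n_taxa):
        total = 0
        for pat in patterns:
            cost = np.zeros(len(labelings), dtype=np.int32)
            for u, v in edges:
                if u < n_taxa and v >= n_taxa:
                    b = pat.states.get(name_of[u])
                    if b is not None:
                        cost += labelings[:, v - n_taxa] != base_code[b]
                elif u >= n_taxa and v >= n_taxa:
                    cost += labelings[:, u - n_taxa] != labelings[:, v - n_taxa]
                else:  # leaf-leaf cannot occur for n >= 3
                    raise AssertionError
            total += int(cost.min())
        best_overall = total if best_overall is None else \
            min(best_overall, total)
    return best_overall
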