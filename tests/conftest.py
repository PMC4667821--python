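"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the implementation paths they check: MRCA ages
come from explicit root-to-tip node paths, PD from the union of pairwise path
edge sets, AvTD from a full pairwise distance matrix, and the likelihood from
a literal term-by-term formula evaluation in plain floats.
"""

import math

import numpy as np
import pytest

from phyloskew import BirthDeathParams, TimeTree, simulate_tree


# -- oracles ------------------------------------------------------------------


def _node_paths(time_tree: TimeTree):
    """Map tip label -> list of nodes from root to that tip."""
    paths = {}
    dtree = time_tree.dendropy_tree
    for leaf in dtree.leaf_node_iter():
        path = []
        nd = leaf
        while nd is not None:
            path.append(nd)
            nd = nd.parent_node
        paths[leaf.taxon.label] = list(reversed(path))
    return paths


def mrca_age_table(time_tree: TimeTree):
    """Exhaustive pairwise MRCA ages from root-to-tip paths."""
    paths = _node_paths(time_tree)
    labels = sorted(paths)
    out = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            shared = None
            for x, y in zip(paths[a], paths[b]):
                if x is y:
                    shared = x
                else:
                    break
            out[(a, b)] = shared.age
    return out


def brute_pd(time_tree: TimeTree, members):
    """PD as the union of edge sets of all pairwise tip-to-tip paths."""
    paths = _node_paths(time_tree)
    members = sorted(members)
    edges = set()
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            pa, pb = paths[a], paths[b]
            k = 0
            while k < min(len(pa), len(pb)) and pa[k] is pb[k]:
                k += 1
            for nd in pa[k:]:
                edges.add(id(nd))
            for nd in pb[k:]:
                edges.add(id(nd))
    by_id = {id(nd): nd for nd in time_tree.dendropy_tree.preorder_node_iter()}
    return sum(by_id[e].edge.length for e in edges)


def brute_distance_matrix(time_tree: TimeTree, members):
    """Patristic distances from depth sums along explicit paths."""
    paths = _node_paths(time_tree)
    members = sorted(members)
    dist = {}
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            pa, pb = paths[a], paths[b]
            k = 0
            while k < min(len(pa), len(pb)) and pa[k] is pb[k]:
                k += 1
            d = sum(nd.edge.length for nd in pa[k:]) + sum(
                nd.edge.length for nd in pb[k:]
            )
            dist[(a, b)] = d
    return dist


def naive_log_likelihood(times, lam, mu, rho):
    """Literal re-evaluation of the ordered-divergence-times likelihood."""
    s = len(times) + 1
    if s == 2:
        return 0.0
    t1 = times[0]

    def P(t):
        return rho * (lam - mu) / (
            rho * lam + (lam * (1 - rho) - mu) * math.exp((mu - lam) * t)
        )

    def p1(t):
        return (1.0 / rho) * P(t) ** 2 * math.exp((mu - lam) * t)

    def v(t):
        return 1.0 - (1.0 / rho) * P(t) * math.exp((mu - lam) * t)

    ll = math.lgamma(s - 1)
    for tj in times[1:]:
        ll += math.log(lam * p1(tj) / v(t1))
    return ll


# -- fixtures -----------------------------------------------------------------


@pytest.fixture(scope="session")
def toy_tree():
    """Three-tip tree ((A:1,B:1):1,C:2); root age 2, one node at age 1."""
    return TimeTree.from_string("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def random_trees_8tip():
    """Twenty small simulated trees for exhaustive-subset oracle checks."""
    bd = BirthDeathParams(3.0, 1.0, 1.0)
    return [simulate_tree(8, bd, seed=100 + i, root_age=1.0) for i in range(20)]


@pytest.fixture(scope="session")
def shark_scale_tree():
    """A 236-tip meta-community tree at the shark-analysis parameter scale."""
    return simulate_tree(236, BirthDeathParams(17.0, 6.0, 1.0), seed=7, root_age=1.0)
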