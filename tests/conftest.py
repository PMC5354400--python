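"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive)
# ---------------------------------------------------------------------------

def bh_step_up_brute(p):
    """Brute-force Benjamini-Hochberg step-up, by direct enumeration."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for rank_i in range(m):
        q_sorted[rank_i] = min(
            min(p[order[j]] * m / (j + 1) for j in range(rank_i, m)), 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def hypergeom_upper_tail_brute(N, K, n, k):
    """P(X >= k) for the hypergeometric by summing the pmf exactly."""
    denom = math.comb(N, n)
    total = 0
    for i in range(k, min(K, n) + 1):
        if n - i <= N - K:
            total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / denom


def reverse_bfs_levels(edges, function_degs, eligible):
    """Breadth-first distance to the DEG layer over reversed edges.

    Paths may only pass through ``eligible`` (non-DEG) nodes, matching
    the rule that only candidate or upstream regulators can occupy
    intermediate levels.
    """
    g = nx.DiGraph()
    g.add_edges_from((s, t) for s, t, *_ in edges)
    levels = {d: 0 for d in function_degs if d in g or True}
    frontier = set(function_degs)
    dist = 0
    while frontier:
        dist += 1
        nxt = set()
        for node in frontier:
            if node not in g:
                continue
            for pred in g.predecessors(node):
                if pred in eligible and pred not in levels:
                    nxt.add(pred)
        for n in nxt:
            levels[n] = dist
        frontier = nxt
    return levels


def pooled_t_brute(a, b):
    """Two-sample pooled-variance t statistic, from the textbook formula."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / \
        (na + nb - 2)
    return (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def expression_bundle():
    from ductnet.simulate import gen_expression_matrix

    matrix, groups, truth = gen_expression_matrix(
        n_genes=1000, n_de=100, effect=4.0, n_per_group=3,
        noise_sd=0.25, seed=11)
    return matrix, groups, truth


@pytest.fixture(scope="session")
def multifunction():
    from ductnet.simulate import gen_multifunction_fixture

    return gen_multifunction_fixture(n_functions=4, n_shared=5,
                                     n_private=3, n_pathway_shared=2,
                                     seed=7)


@pytest.fixture(scope="session")
def noiseless_tree():
    from ductnet.simulate import gen_wholemount_image

    return gen_wholemount_image(depth=3, noise_sd=0.0, seed=4)
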