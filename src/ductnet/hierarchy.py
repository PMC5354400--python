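"""Hierarchical regulator networks over relation-typed digraphs.

The knowledge-base export is a directed graph whose edges carry one of
three regulation labels — affected, activated or inhibited — and is
equivalently three adjacency matrices over one shared node index. For
one cellular function, the layered network downstream of the
overexpressed receptor is built iteratively: level 0 is the function's
DEGs; level 1 is every candidate regulator with a direct edge into a
DEG; level i+1 is every not-yet-assigned candidate with a direct edge
into level i; iteration stops at the first round that adds nothing.
This fixpoint is exactly minimal-distance layering: a node's level is
its shortest directed distance to the DEG layer, ties resolving to the
smaller level. Relation labels never influence the layering — all three
count as regulation — and are preserved only as edge annotations.

Comparing the per-function networks gives each node a multiplicity (the
number of networks assigning it an intermediate or upstream level); the
nodes present in every network, optionally intersected with the members
of the enriched signaling pathways, are the common intermediate
regulators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

__all__ = ["RELATIONS", "TypedRegGraph", "HierarchicalNetwork",
           "ingest_graph", "build_hierarchy", "network_multiplicity",
           "common_intermediates"]

RELATIONS = ("affected", "activated", "inhibited")

log = logging.getLogger(__name__)


@dataclass
class TypedRegGraph:
    """Directed regulation graph with role tags and typed edges."""

    graph: nx.DiGraph = field(repr=False)
    degs: set = field(default_factory=set)
    upstream: set = field(default_factory=set)

    @property
    def candidates(self):
        """Nodes eligible for intermediate levels (non-DEG nodes)."""
        return set(self.graph.nodes) - self.degs

    def adjacency_matrices(self):
        """The three {relation: adjacency matrix} views, shared index."""
        import numpy as np
        nodes = sorted(self.graph.nodes)
        idx = {n: i for i, n in enumerate(nodes)}
        mats = {r: np.zeros((len(nodes), len(nodes)), dtype=bool)
                for r in RELATIONS}
        for s, t, d in self.graph.edges(data=True):
            mats[d["relation"]][idx[s], idx[t]] = True
        return nodes, mats


@dataclass
class HierarchicalNetwork:
    """One function's layered regulator network."""

    function_label: str
    level_of: dict                      # node -> int (0 = DEG layer)
    edges: list                         # (source, target, relation)
    iterations_to_fixpoint: int
    upstream: set = field(default_factory=set)

    @property
    def n_levels(self):
        return max(self.level_of.values(), default=0)

    def nodes_at(self, level):
        return {n for n, lv in self.level_of.items() if lv == level}

    @property
    def intermediates(self):
        """All nodes with a positive level (incl. upstream regulators)."""
        return {n for n, lv in self.level_of.items() if lv >= 1}


def ingest_graph(edge_table, deg_list=(), upstream=()):
    """Build a TypedRegGraph from (source, target, relation) rows.

    Unknown relation labels are rejected with the offending row number;
    self-loops are dropped and duplicate triples collapsed (both with a
    logged count). Nodes are created on first mention; declared DEG and
    upstream ids are added even when no edge touches them.
    """
    g = nx.DiGraph()
    n_self = n_dup = 0
    for i, row in enumerate(edge_table):
        s, t, rel = row[0], row[1], row[2]
        if rel not in RELATIONS:
            raise ValueError(
                f"row {i}: unknown relation {rel!r} "
                f"(expected one of {', '.join(RELATIONS)})")
        if s == t:
            n_self += 1
            continue
        if g.has_edge(s, t) and g[s][t]["relation"] == rel:
            n_dup += 1
            continue
        g.add_edge(s, t, relation=rel)
    if n_self:
        log.info("dropped %d self-loop(s)", n_self)
    if n_dup:
        log.info("collapsed %d duplicate triple(s)", n_dup)
    g.add_nodes_from(deg_list)
    g.add_nodes_from(upstream)
    return TypedRegGraph(graph=g, degs=set(deg_list), upstream=set(upstream))


def build_hierarchy(graph, function_degs, function_label=""):
    """Layer the regulators controlling one function's DEGs.

    Level 0 is ``function_degs``; each iteration assigns level i+1 to
    every unassigned candidate (or upstream) node with at least one
    outgoing edge, of any relation type, into level i, and stops when a
    round adds no node. Nodes without a directed path into the DEG layer
    are excluded. Retained edges run from an assigned node into any
    strictly lower assigned level.
    """
    function_degs = set(function_degs)
    if not function_degs:
        log.warning("empty DEG set for function %r: empty network",
                    function_label)
        return HierarchicalNetwork(function_label, {}, [], 0,
                                   upstream=set())
    missing = function_degs - graph.degs
    if missing:
        raise ValueError(
            f"function DEGs not tagged as DEGs in the graph: "
            f"{sorted(missing)[:5]}")

    eligible = graph.candidates           # intermediates come from non-DEGs
    level_of = {n: 0 for n in function_degs}
    frontier = function_degs
    iterations = 0
    while True:
        iterations += 1
        nxt = set()
        for node in frontier:
            for pred in graph.graph.predecessors(node):
                if pred in eligible and pred not in level_of:
                    nxt.add(pred)
        if not nxt:
            break
        lv = level_of[next(iter(frontier))] + 1
        for n in nxt:
            level_of[n] = lv
        frontier = nxt

    edges = sorted(
        (s, t, d["relation"])
        for s, t, d in graph.graph.edges(data=True)
        if s in level_of and t in level_of and level_of[s] > level_of[t])
    return HierarchicalNetwork(
        function_label=function_label,
        level_of=dict(sorted(level_of.items())),
        edges=edges,
        iterations_to_fixpoint=iterations,
        upstream=graph.upstream & set(level_of),
    )


def network_multiplicity(networks):
    """Node -> number of networks assigning it an intermediate level.

    DEG-layer (level 0) membership does not count: the comparison is
    about shared *regulators*, and a gene can be a DEG for one function
    and an intermediate for another.
    """
    if len(networks) < 2:
        raise ValueError("need at least 2 networks to compare")
    counts = {}
    for net in networks:
        for node in net.intermediates:
            counts[node] = counts.get(node, 0) + 1
    return dict(sorted(counts.items()))


def common_intermediates(multiplicity, n_networks, pathway_members=None,
                         min_count=None):
    """Nodes found in (by default) every network.

    ``min_count`` relaxes the full-membership rule; ``pathway_members``
    restricts the result to regulators that belong to the enriched
    signaling pathways, mirroring the selection of candidates for
    experimental follow-up.
    """
    threshold = n_networks if min_count is None else min_count
    common = {n for n, c in multiplicity.items() if c >= threshold}
    if pathway_members is not None:
        common &= set(pathway_members)
    return set(sorted(common))
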