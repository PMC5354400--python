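"""Gene-set over-representation against a DEG list.

For each gene set the overlap k between the DEG list (size n) and the
set (size K, after restriction to the N-gene universe) is scored with
the one-sided upper-tail hypergeometric probability P(X >= k), and the
"affected proportion" k / K — the fraction of the set's genes that are
differentially expressed — is reported alongside. The universe is all
genes on the array. Over-representation only; depletion is out of
scope, and no correction is applied across sets by default (a BH option
is exposed but off).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .degs import bh_adjust

__all__ = ["EnrichmentRow", "overlap_test", "affected_proportion",
           "rank_sets", "enrich_collection"]

log = logging.getLogger(__name__)


@dataclass
class EnrichmentRow:
    set_id: str
    K: int          # set size within the universe
    n: int          # DEG-list size
    N: int          # universe size
    k: int          # overlap
    p_hyper: float
    affected_proportion: float


def overlap_test(deg_list, gene_set, universe, set_id="set"):
    """Hypergeometric over-representation of one gene set.

    ``p_hyper`` is the exact probability of drawing >= k members of the
    set when n genes are drawn without replacement from the N-gene
    universe, K of which belong to the set. Set members outside the
    universe are dropped (with a debug log of the count); DEG genes
    outside the universe are an error.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    deg = set(deg_list)
    stray = deg - universe
    if stray:
        raise ValueError(
            f"DEG gene(s) absent from the universe: {sorted(stray)[:5]}")
    members = set(gene_set)
    dropped = len(members - universe)
    if dropped:
        log.debug("%s: %d member(s) outside the universe dropped",
                  set_id, dropped)
    members &= universe

    N, K, n = len(universe), len(members), len(deg)
    k = len(members & deg)
    p = float(hypergeom.sf(k - 1, N, K, n))
    prop = k / K if K else 0.0
    return EnrichmentRow(set_id=set_id, K=K, n=n, N=N, k=k,
                         p_hyper=min(p, 1.0), affected_proportion=prop)


def affected_proportion(gene_set, deg_list):
    """Fraction of the set's members that are in the DEG list."""
    members = set(gene_set)
    if not members:
        raise ValueError("gene set is empty")
    return len(members & set(deg_list)) / len(members)


def rank_sets(collection, deg_list, universe, top=None, bh=False):
    """Score every set in ``collection`` and rank them.

    ``collection`` is a ``{set_id: members}`` mapping. Rows are sorted
    by ascending p_hyper, ties broken by descending affected proportion
    then lexicographic set id; ``top`` truncates the ranking. With
    ``bh=True`` a BH-adjusted column is appended (off by default: the
    ranking statistic itself stays the raw overlap p).
    """
    if not collection:
        raise ValueError("gene-set collection is empty")
    rows = [overlap_test(deg_list, members, universe, set_id=sid)
            for sid, members in collection.items()]
    rows.sort(key=lambda r: (r.p_hyper, -r.affected_proportion, r.set_id))
    df = pd.DataFrame([r.__dict__ for r in rows])
    if bh:
        df["p_adj"] = bh_adjust(df["p_hyper"].to_numpy())
    return df.head(top) if top else df


def enrich_collection(collection, deg_list, universe, top=None, bh=False):
    """Alias of rank_sets kept for pipeline readability."""
    return rank_sets(collection, deg_list, universe, top=top, bh=bh)
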