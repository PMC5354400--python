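"""Rank gene sets by hypergeometric overlap with a DEG list.

Plants one set whose members are 80% DEGs among nine random sets and
shows that the overlap test pulls it to the top of the ranking.
"""

from ductnet import (
    deg_screen,
    gen_expression_matrix,
    gen_geneset_collection,
    rank_sets,
)
from ductnet.degs import deg_list

matrix, groups, _ = gen_expression_matrix(seed=2)
degs = deg_list(deg_screen(matrix, groups))
universe = list(matrix.index)

collection = gen_geneset_collection(
    universe, n_sets=10, size_range=(30, 30),
    planted_enriched=(0, 0.8), deg_list=degs, seed=2)

ranked = rank_sets(collection, degs, universe, top=4)
print(ranked.round(4).to_string(index=False))
# p_hyper is the exact upper-tail probability of observing at least k
# of the set's K genes among the n DEGs drawn from the N-gene array;
# affected_proportion (k/K) is the fraction of the set that responded.
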