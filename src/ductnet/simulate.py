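"""Synthetic inputs with known ground truth.

Generators for the four kinds of input the analysis arms consume:

* two-group expression matrices with planted differential expression,
  emulating RMA-normalised triplicate array intensities;
* gene-set collections (GO-BP / KEGG-like) with an optionally planted
  enriched set;
* relation-typed regulatory digraphs with planted hierarchy levels;
* rendered whole-mount images of a branching ductal tree (dark ducts on
  a light background, as in carmine-stained glands).

Every generator is a pure function of its parameters and an integer seed,
and returns the generated object together with a truth record from which
all ground-truth quantities can be recomputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionTruth",
    "GraphTruth",
    "TreeTruth",
    "gen_expression_matrix",
    "gen_geneset_collection",
    "gen_regulatory_graph",
    "gen_multifunction_fixture",
    "gen_wholemount_image",
]

RELATIONS = ("affected", "activated", "inhibited")


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTruth:
    """Planted differential-expression ground truth."""

    de_genes: set
    effect: float
    direction: dict          # gene -> "up" | "down"
    noise_sd: float
    seed: int

    def __post_init__(self):
        if self.effect <= 1:
            raise ValueError("effect must be a linear fold ratio > 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gen_expression_matrix(n_genes=1000, n_de=100, effect=4.0, n_per_group=3,
                          noise_sd=0.25, seed=0):
    """Simulate a two-group gene x sample intensity matrix.

    Per-gene baselines are drawn uniformly in [6, 12] log2 units (the
    dynamic range of normalised arrays); samples add Gaussian noise of
    ``noise_sd`` on the log2 scale. ``n_de`` genes are shifted by
    ``log2(effect)`` in group B, half up and half down (direction chosen
    at random per gene). Values are returned on the linear scale.

    Returns
    -------
    (pandas.DataFrame, dict, ExpressionTruth)
        The matrix (rows genes, columns ``A1..An,B1..Bn``), a sample ->
        group-label mapping, and the truth record.
    """
    if n_de > n_genes:
        raise ValueError(f"n_de ({n_de}) exceeds n_genes ({n_genes})")
    if effect <= 1:
        raise ValueError("effect must be > 1 (linear fold ratio)")
    if n_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    rng = np.random.default_rng(seed)

    genes = [f"G{i:05d}" for i in range(n_genes)]
    baseline = rng.uniform(6.0, 12.0, size=n_genes)
    log2 = baseline[:, None] + rng.normal(0.0, noise_sd,
                                          size=(n_genes, 2 * n_per_group))

    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    up = rng.random(n_de) < 0.5
    shift = np.where(up, 1.0, -1.0) * math.log2(effect)
    log2[de_idx, n_per_group:] += shift[:, None]

    cols = [f"A{i + 1}" for i in range(n_per_group)] + \
           [f"B{i + 1}" for i in range(n_per_group)]
    matrix = pd.DataFrame(2.0 ** log2, index=genes, columns=cols)
    groups = {c: ("A" if c.startswith("A") else "B") for c in cols}
    direction = {genes[i]: ("up" if u else "down")
                 for i, u in zip(de_idx, up)}
    truth = ExpressionTruth(de_genes=set(direction), effect=float(effect),
                            direction=direction, noise_sd=float(noise_sd),
                            seed=int(seed))
    return matrix, groups, truth


# ---------------------------------------------------------------------------
# gene-set collections
# ---------------------------------------------------------------------------

def gen_geneset_collection(universe, n_sets=10, size_range=(20, 100),
                           planted_enriched=None, deg_list=None, seed=0):
    """Sample ``n_sets`` gene sets from ``universe``.

    ``planted_enriched`` is an optional ``(set_index, overlap_fraction)``
    pair: the designated set then draws ``round(fraction * size)`` of its
    members from ``deg_list`` and the remainder from outside it, so its
    overlap with the DEG list is known by construction.

    Returns an ordered ``{set_id: set of genes}`` mapping.
    """
    universe = list(universe)
    if not universe:
        raise ValueError("universe is empty")
    lo, hi = size_range
    if hi > len(universe):
        raise ValueError("max set size exceeds universe size")
    rng = np.random.default_rng(seed)

    collection = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        set_id = f"SET{i:03d}"
        if planted_enriched is not None and i == planted_enriched[0]:
            if deg_list is None:
                raise ValueError("planting an enriched set requires deg_list")
            frac = planted_enriched[1]
            degs = sorted(set(deg_list))
            others = sorted(set(universe) - set(degs))
            k = round(frac * size)
            if k > len(degs) or size - k > len(others):
                raise ValueError("requested planted overlap is infeasible")
            members = set(rng.choice(degs, size=k, replace=False)) | \
                set(rng.choice(others, size=size - k, replace=False))
        else:
            members = set(rng.choice(universe, size=size, replace=False))
        collection[set_id] = members
    return collection


# ---------------------------------------------------------------------------
# layered regulatory graphs
# ---------------------------------------------------------------------------

@dataclass
class GraphTruth:
    """Planted hierarchy: node -> level (0 = DEG layer, top = upstream)."""

    planted_levels: dict
    relations: dict          # (source, target) -> relation label
    seed: int

    @property
    def n_levels(self):
        return max(self.planted_levels.values())


def gen_regulatory_graph(n_levels=3, nodes_per_level=10,
                         extra_noise_edges=0, seed=0):
    """Build a relation-typed digraph with a planted level structure.

    Level 0 holds DEGs; levels 1..n_levels hold regulators, the top level
    playing the upstream-regulator role. Every planted edge runs from a
    level-(i+1) node to a level-i node, so the minimal distance of a node
    to the DEG layer equals its planted level. Noise edges are sampled
    only between node pairs that cannot shorten any node's distance to
    the DEG layer (target level >= source level - 1), keeping the planted
    layering recoverable.

    Returns
    -------
    (list of (source, target, relation), GraphTruth)
    """
    if n_levels < 1 or nodes_per_level < 1:
        raise ValueError("n_levels and nodes_per_level must be >= 1")
    rng = np.random.default_rng(seed)

    levels = {}
    for lv in range(n_levels + 1):
        prefix = "G" if lv == 0 else ("U" if lv == n_levels else f"R{lv}")
        for i in range(nodes_per_level):
            levels[f"{prefix}_{i:03d}"] = lv
    by_level = {lv: sorted(n for n, l in levels.items() if l == lv)
                for lv in range(n_levels + 1)}

    relations = {}
    for lv in range(1, n_levels + 1):
        for node in by_level[lv]:
            n_out = int(rng.integers(1, min(3, nodes_per_level) + 1))
            targets = rng.choice(by_level[lv - 1], size=n_out, replace=False)
            for t in targets:
                relations[(node, t)] = RELATIONS[rng.integers(3)]

    # noise edges: (u, v) with level(v) >= level(u) - 1 never creates a
    # path to level 0 shorter than level(u)
    nodes = sorted(levels)
    added = 0
    attempts = 0
    while added < extra_noise_edges and attempts < 100 * (extra_noise_edges + 1):
        attempts += 1
        u, v = rng.choice(nodes, size=2, replace=False)
        if levels[v] < levels[u] - 1 or (u, v) in relations:
            continue
        relations[(u, v)] = RELATIONS[rng.integers(3)]
        added += 1

    edges = [(s, t, r) for (s, t), r in sorted(relations.items())]
    return edges, GraphTruth(planted_levels=levels, relations=relations,
                             seed=int(seed))


def gen_multifunction_fixture(n_functions=4, n_shared=5, n_private=3,
                              degs_per_function=6, n_pathway_shared=2,
                              deg_ids=None, seed=0):
    """Shared graph + per-function DEG sets with planted common regulators.

    ``n_shared`` intermediate regulators feed DEGs of every function;
    each function additionally has ``n_private`` intermediates of its
    own, and one upstream regulator sits above all intermediates.
    ``n_pathway_shared`` of the shared intermediates are tagged as
    members of the enriched signaling pathways, emulating the selection
    of candidates for experimental follow-up. ``deg_ids`` optionally
    supplies the gene ids to use as function DEGs (disjoint chunks, so
    the fixture can be wired to the genes of a simulated expression
    matrix); synthetic ids are invented otherwise.

    Returns a dict with keys ``edges``, ``function_degs`` (name -> DEG
    set), ``upstream``, ``shared`` (the planted common intermediates),
    ``pathway_members`` and ``private`` (name -> its own intermediates).
    """
    rng = np.random.default_rng(seed)
    shared = [f"SH_{i}" for i in range(n_shared)]
    upstream = ["UP_0"]
    function_degs, private = {}, {}
    relations = {}

    if deg_ids is not None and len(deg_ids) < n_functions * degs_per_function:
        raise ValueError("deg_ids too short for the requested functions")
    for f in range(n_functions):
        name = f"fn{f}"
        if deg_ids is None:
            degs = [f"D{f}_{i}" for i in range(degs_per_function)]
        else:
            degs = list(deg_ids[f * degs_per_function:
                                (f + 1) * degs_per_function])
        priv = [f"P{f}_{i}" for i in range(n_private)]
        function_degs[name] = set(degs)
        private[name] = set(priv)
        n_hit = min(3, degs_per_function)
        for node in shared + priv:
            # each regulator hits several of this function's DEGs
            for t in rng.choice(degs, size=n_hit, replace=False):
                relations[(node, t)] = RELATIONS[rng.integers(3)]
        for node in shared + priv:
            relations[(upstream[0], node)] = RELATIONS[rng.integers(3)]

    edges = [(s, t, r) for (s, t), r in sorted(relations.items())]
    return {
        "edges": edges,
        "function_degs": function_degs,
        "upstream": set(upstream),
        "shared": set(shared),
        "pathway_members": set(shared[:n_pathway_shared]),
        "private": private,
    }


# ---------------------------------------------------------------------------
# whole-mount ductal-tree images
# ---------------------------------------------------------------------------

@dataclass
class TreeTruth:
    """Ground truth for a rendered ductal tree.

    ``segments`` stores, per duct segment, the ordered pixel coordinates
    of its digitized centerline; topology counts and lengths are
    recomputable from it. ``total_length_px`` is the chain-code length of
    the digitized centerlines (1 per orthogonal step, sqrt(2) per
    diagonal step); ``total_length_mm`` applies ``pixel_size``.
    ``n_tip`` counts distal leaf tips; the root base is an additional
    skeleton endpoint and is not included.
    """

    segments: list = field(repr=False)     # list of (N,2) int arrays
    children: dict = field(repr=False)     # segment index -> child indices
    n_branch: int = 0
    n_tip: int = 0
    total_length_px: float = 0.0
    total_length_mm: float = 0.0
    tube_width: float = 1.0
    pixel_size: float = 1.0
    noise_sd: float = 0.0
    clipped: bool = False
    seed: int = 0

    def recompute_counts(self):
        """Re-derive (n_branch, n_tip) by walking the stored topology."""
        n_branch = sum(1 for c in self.children.values() if len(c) >= 2)
        n_tip = sum(1 for i in range(len(self.segments))
                    if not self.children.get(i))
        return n_branch, n_tip

    def recompute_length_px(self):
        """Chain-code length of all stored centerline pixels."""
        total = 0.0
        for seg in self.segments:
            d = np.abs(np.diff(seg.astype(float), axis=0))
            total += float(np.sum(np.where(d.sum(axis=1) == 2.0,
                                           math.sqrt(2.0), 1.0)))
        return total


def _grow_tree_once(rng, depth, seg_len_range, angle_jitter, branch_prob):
    lo, hi = seg_len_range
    segments = []          # (start, end) float pairs
    children = {}

    def new_segment(start, angle, level):
        length = rng.uniform(lo, hi)
        end = (start[0] - length * math.cos(math.radians(angle)),
               start[1] + length * math.sin(math.radians(angle)))
        idx = len(segments)
        segments.append((start, end))
        children[idx] = []
        if level < depth and rng.random() < branch_prob:
            for sign in (-1, 1):
                child_angle = angle + sign * (30.0 + rng.uniform(
                    -angle_jitter, angle_jitter))
                children[idx].append(
                    new_segment(end, child_angle, level + 1))
        return idx

    new_segment((0.0, 0.0), 0.0, 0)
    return segments, children


def _segments_collide(segments, children, min_sep):
    """True if two segments that share no node come within ``min_sep``.

    Real ductal trees are open (non-anastomosing); a collision would
    merge two tubes in the rendered image and corrupt the planted
    topology, so colliding draws are rejected.
    """
    from scipy.spatial.distance import cdist

    adjacent = set()
    for parent, kids in children.items():
        for k in kids:
            adjacent.add(frozenset((parent, k)))
        for a in kids:
            for b in kids:
                if a != b:
                    adjacent.add(frozenset((a, b)))

    samples = []
    for (start, end) in segments:
        start, end = np.asarray(start), np.asarray(end)
        n = max(int(np.linalg.norm(end - start)), 2)
        t = np.linspace(0.0, 1.0, n)[:, None]
        samples.append(start + t * (end - start))

    for i in range(len(segments)):
        for j in range(i + 1, len(segments)):
            if frozenset((i, j)) in adjacent:
                continue
            if cdist(samples[i], samples[j]).min() < min_sep:
                return True
    return False


def _grow_tree(rng, depth, seg_len_range, angle_jitter, branch_prob,
               min_sep, max_tries=100):
    """Sample a collision-free binary tree of directed segments.

    Segments are (start, end) point pairs in (row, col) space growing
    upward from the origin; a node branches with probability
    ``branch_prob`` while its level is below ``depth``, otherwise its
    segment ends in a tip. Draws whose non-adjacent segments approach
    closer than ``min_sep`` are rejected and redrawn (same rng stream,
    so the result is still a pure function of the seed).
    """
    for _ in range(max_tries):
        segments, children = _grow_tree_once(rng, depth, seg_len_range,
                                             angle_jitter, branch_prob)
        if not _segments_collide(segments, children, min_sep):
            return segments, children
    raise RuntimeError("could not draw a collision-free tree; loosen the "
                       "geometry (longer segments or narrower tubes)")


def gen_wholemount_image(depth=3, segment_length=(40, 60), tube_width=5.0,
                         angle_jitter=10.0, branch_prob=0.9, noise_sd=0.0,
                         pixel_size=0.01, background=0.85, contrast=0.6,
                         shape=None, seed=0):
    """Render a random binary-branching ductal tree as a grayscale image.

    The tree grows upward from a root; each segment is drawn as a tube of
    Gaussian cross-section (sigma = tube_width / 2, truncated at 3 sigma)
    that darkens the light background, matching the polarity of a
    carmine-stained whole mount. Additive Gaussian pixel noise of
    ``noise_sd`` is applied last and the image clipped to [0, 1].

    When ``shape`` is None the canvas is sized to fit the whole tree; a
    fixed ``shape`` that cannot contain it sets ``truth.clipped``.

    Returns
    -------
    (numpy.ndarray float64 in [0,1], numpy.ndarray bool, TreeTruth)
        The image, the true tube-support mask (centerline distance
        <= tube_width / 2), and the truth record.
    """
    if tube_width < 1:
        raise ValueError("tube_width must be >= 1 px")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    from skimage.draw import line as draw_line
    from scipy.ndimage import distance_transform_edt

    rng = np.random.default_rng(seed)
    pts, children = _grow_tree(rng, depth, segment_length, angle_jitter,
                               branch_prob, min_sep=2.0 * tube_width + 4.0)

    coords = np.array([p for seg in pts for p in seg])
    margin = int(3 * tube_width) + 4
    r0, c0 = coords.min(axis=0) - margin
    r1, c1 = coords.max(axis=0) + margin
    clipped = False
    if shape is None:
        shape = (int(math.ceil(r1 - r0)) + 1, int(math.ceil(c1 - c0)) + 1)
        offset = (-r0, -c0)
    else:
        offset = (-r0, -c0)
        if r1 - r0 >= shape[0] or c1 - c0 >= shape[1]:
            clipped = True

    segments = []
    centerline = np.zeros(shape, dtype=bool)
    for (start, end) in pts:
        sr = int(round(start[0] + offset[0]))
        sc = int(round(start[1] + offset[1]))
        er = int(round(end[0] + offset[0]))
        ec = int(round(end[1] + offset[1]))
        rr, cc = draw_line(sr, sc, er, ec)
        inside = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        if not inside.all():
            clipped = True
        rr, cc = rr[inside], cc[inside]
        segments.append(np.column_stack([rr, cc]))
        centerline[rr, cc] = True

    dist = distance_transform_edt(~centerline)
    sigma = tube_width / 2.0
    dip = contrast * np.exp(-dist ** 2 / (2.0 * sigma ** 2))
    dip[dist > 3.0 * sigma] = 0.0
    image = np.clip(background - dip, 0.0, 1.0)
    if noise_sd > 0:
        image = np.clip(image + rng.normal(0.0, noise_sd, size=shape),
                        0.0, 1.0)
    tube_mask = dist <= tube_width / 2.0

    truth = TreeTruth(segments=segments, children=children,
                      tube_width=float(tube_width),
                      pixel_size=float(pixel_size),
                      noise_sd=float(noise_sd), clipped=clipped,
                      seed=int(seed))
    truth.n_branch, truth.n_tip = truth.recompute_counts()
    truth.total_length_px = truth.recompute_length_px()
    truth.total_length_mm = truth.total_length_px * pixel_size
    return image, tube_mask, truth
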