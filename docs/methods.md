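# Methods

## Differential-expression screen

The screen takes a genes × samples matrix of positive linear
intensities (log2 input accepted behind a flag) with a two-group
design of at least two samples per group. Per gene it reports the
group means, the *variation factor* — the folded linear ratio
`max(r, 1/r)`, `r = mean_B/mean_A`, so a single threshold covers up-
and down-regulation — a direction, and a two-sided two-sample t-test
on log2 intensities. Benjamini–Hochberg step-up adjustment
(`q_(i) = min_{j≥i} p_(j)·m/j`, capped at 1) controls the FDR across
genes, and a gene is called when the variation factor is **≥ 2.3**
(non-strict) and the adjusted p is **< 0.05** (strict), mirroring the
printed thresholds.

The per-gene test is the pooled-variance Student t by default, with
Welch behind `welch=True`. The choice matters at triplicate scale:
Welch's Satterthwaite degrees of freedom collapse toward 2 when n = 3,
and in the package's own operating-characteristics simulation (1000
genes, 100 planted at fold 4, log2 noise SD 0.25, triplicates) it
costs roughly 30 points of sensitivity relative to the pooled test at
an identical (zero) empirical false-discovery proportion. The unpaired
Student test is also the one named test in the study design this
package models. Equal-variance pooling is an assumption, not a fact,
of the data; with simulated homoscedastic log2 noise it is exact.
Degenerate genes with zero variance in both groups get p = 1 when the
means agree and p = 0 with a warning when they do not, so NaNs never
propagate.

Whether the original analysis tested on the log2 or linear scale, and
which scale the 2.3 factor applied to, is not documented anywhere we
could follow; the conventions above (test on log2, ratio on linear)
are this package's own and are stated rather than asserted as the
original intent.

## Gene-set over-representation

The universe is every gene on the array (all matrix rows). For each
set, members outside the universe are dropped with a logged count;
`p_hyper` is the exact upper-tail hypergeometric probability of at
least the observed overlap, and the affected proportion k/K is
reported alongside, since a highly significant overlap can still touch
a small fraction of a large set. Ranking is by ascending p, ties by
descending affected proportion then set id. Only over-representation
is scored; no correction is applied across sets by default (the
ranking statistic is the raw overlap p, as in the online tools this
emulates), with BH available behind a flag.

## Hierarchical regulator networks

The interaction knowledge base is modelled as a directed graph whose
edges carry exactly one of three relation labels (affected, activated,
inhibited) — equivalently three boolean adjacency matrices over a
shared node index, which the `TypedRegGraph.adjacency_matrices` view
exposes. Ingestion drops self-loops, collapses duplicate triples, and
rejects unknown labels with the offending row number. The candidate
set for intermediate levels is an explicit input: every non-DEG node
of the supplied graph. The package deliberately does not infer
candidates, because in the emulated workflow the regulator list comes
from an upstream prediction step that is out of scope.

Layering is the iterative fixpoint described above; it terminates in
at most |nodes| + 1 iterations because each productive iteration
assigns at least one node. It is provably identical to multi-source
reverse breadth-first distance from the function's DEG layer (the test
suite checks this equivalence on random digraphs up to 1000 nodes),
which also gives the tie rule for free: a node reachable at two depths
takes the smaller one. Relation labels never influence level
assignment — all three count as regulation — and survive only as edge
attributes in the GraphML/TSV exports. Declared upstream regulators
are eligible for any level and carry a tag so exports can highlight
them.

Multiplicity counts, per node, the networks that assign it a level
≥ 1. DEG-layer membership does not count: the output of the comparison
is a list of common *regulators*, and a gene may be a DEG for one
function while regulating another. The common-intermediate rule is
count = n_networks, with the threshold configurable (`min_count`) and
an optional intersection with the members of the enriched signaling
pathways.

## Whole-mount quantification

Images are 2-D grayscale in [0, 1] with an explicit polarity; stained
ducts are darker than background, and `ducts_dark` input is inverted
internally so the bright-ridge rule applies. Vesselness per scale σ:
Gaussian-derivative Hessian times σ² (scale normalisation), eigenvalues
ordered |λ1| ≤ |λ2|, response 0 where λ2 > 0 and otherwise
`exp(−R_b²/2β²)·(1−exp(−S²/2c²))` with R_b = λ1/λ2 and
S = √(λ1²+λ2²); the final response is the pixel-wise maximum over
scales. Defaults: β = 0.5 (the standard blobness setting of the
original filter), c = half the maximum Hessian Frobenius norm per
scale (contrast-adaptive; an absolute value can be supplied), sigmas a
geometric series 1–8 px. Scales should bracket the expected duct
half-width; the test fixtures use 1–3 px for their 5-px tubes. Two
numerical details matter: derivative kernels are truncated at 8σ
because the default 4σ truncation does not annihilate constants and
leaks the image's DC level into S on flat regions, and Hessian
magnitudes below 10⁻¹⁰ of the dynamic range are treated as zero so a
constant image returns an exactly zero response.

Segmentation is `response ≥ threshold` with Otsu's threshold by
default (reproducible and parameter-free) or a fixed value in [0, 1];
8-connected components under `min_object_px` (default 50) are removed
as speckle. Skeletonization is Zhang thinning plus a final
morphological thin pass, which removes the rare 2×2 blocks Zhang
thinning can leave at thick junctions; the metrics routine rejects any
non-thin input. Endpoints have exactly one 8-neighbour; branch pixels
have ≥ 3, and 8-connected clusters of branch pixels count once,
because thinning produces adjacent junction pixels that would
otherwise inflate the count. Extension is the summed chain-code length
(1 / √2 per step) in px and mm; the longest geodesic path per
component is reported as well, since "total extension" could also be
read as the tree's greatest reach. Sprout counts are reported both as
all endpoints and with one endpoint per component subtracted
(`n_sprout_no_root`), because the gland's entry duct contributes an
endpoint that is not a growing tip. Group comparison is the unpaired
Student t-test per metric with means and SEMs.

## Synthetic data

*Expression*: per-gene baselines uniform in [6, 12] log2 units (the
dynamic range of RMA-normalised arrays), i.i.d. Gaussian log2 noise
per sample (default SD 0.25, a typical replicate scatter for good
arrays), and planted genes shifted by ±log2(effect) in group B, half
up and half down. It does not model probe-level effects,
mean–variance trends, correlated genes, or batch structure — so
passing operating characteristics show the screen's behaviour under
clean replicate noise, not under real array artefacts.

*Regulatory graphs*: nodes in consecutive levels with every planted
edge descending exactly one level, relation labels uniform at random,
and optional noise edges sampled only where they cannot shorten any
node's distance to the DEG layer (target level ≥ source level − 1), so
the planted layering stays recoverable by construction.

*Ductal trees*: binary branching from a root growing upward, child
angles = parent ± (30° + jitter), per-level branch probability 0.9 by
default (set it to 1 to plant deterministic topology differences),
segment lengths uniform in 40–60 px, tubes rendered as a Gaussian
cross-section of σ = width/2 truncated at 3σ on a light background,
then additive Gaussian pixel noise. Draws in which two segments that
share no node pass within twice the tube width are rejected and
redrawn: real ductal trees are open, and a collision would silently
corrupt the planted topology. The truth record stores the digitized
centerline pixels per segment; `total_length` is their chain-code
length (matching the skeleton's length metric — the chain length of a
digitized segment exceeds its Euclidean length by up to ~8% at
intermediate angles, so a Euclidean truth would bias every comparison)
and all counts are recomputable from the stored topology. `n_tip`
counts distal tips only; the root base is an extra skeleton endpoint,
which is why truth comparisons use the root-excluded sprout count.
Lobulo-alveolar structures, 3-D effects and uneven staining are not
modelled.

## Assay statistics

Doubling time `t·ln2/ln(Nt/N0)` assumes a constant growth rate between
the two measurements; a declining culture returns a flagged negative
value rather than raising so batch tables never abort. ΔΔCt assumes
equal amplification efficiency of target and reference (no efficiency
correction). The unpaired Student t-test declares significance
strictly below α = 0.05.

## Problem sizes and determinism

Every generator is a pure function of its parameters and one explicit
seed; pipeline runs write a manifest (input SHA-256 hashes, all
parameters, seed, package version) and are byte-identical under
rerun. The test and acceptance workloads use 1000-gene matrices,
graphs up to 1000 nodes, depth-3/4 trees (images of roughly 200–300 px
a side) and 10-seed replication for stochastic quantities — sizes
chosen so the full suite runs in seconds while leaving each statistic
well away from its acceptance bound.

## Known limitations

Probe-level preprocessing (CEL/RMA), GO-graph term propagation,
upstream-regulator prediction and activation scoring, lymph-node
masking and mosaic stitching, duct-diameter profiling, and moderated-
variance differential tests are all out of scope. The vesselness
cross-check against scikit-image must account for that filter's
missing σ² Hessian normalisation (its gamma equals this package's
c/σ² at a single scale).
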