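# Methods

## Graph model

An MPX cell is a bipartite multigraph: A-pixels and B-pixels as the two
node sets, antibody molecules as marker-labeled, counted edges. All
scoring runs on the A-node projection, where two A-pixels are adjacent
iff they share at least one B-pixel and per-marker edge counts are
summed onto the incident A-node. The projection is kept **simple and
unweighted**: sharing several B-pixels does not create parallel edges or
weights, because the assortativity machinery downstream is defined on
adjacency only and projected edge multiplicity has no clear biological
meaning at pixel scale. Projection conserves per-marker totals exactly.

Cells whose projection is disconnected are restricted to the largest
connected component before scoring (random walks with restart are
ill-defined across components); the number of dropped nodes is logged.
Pixel ids are opaque strings with no ordering semantics; node order in
all score vectors is the lexicographic order of A-pixel ids, which makes
every computation independent of input row order.

Cells are exchanged as plain delimited edge lists
(`cell_id, upia, upib, marker, count`) plus a panel manifest
(`marker, is_isotype`). This dialect replaces the proprietary PXL
container, which is out of scope.

## Local assortativity

For marker count vector *x* on a connected projected graph, define the
edge-end (degree-weighted) moments μ_e = Σ_v d_v x_v / Σ_v d_v and
σ_e² = Σ_v d_v x_v² / Σ_v d_v − μ_e². The per-vertex score is

    score(ℓ) = (1/σ_e²) ( Σ_v w_v(ℓ) · x_v · ( Σ_{u∼v} x_u / d_v ) − μ_e² )

with *w(ℓ)* the personalized-PageRank distribution of vertex ℓ. At
`restart_probability = 0` the weights reduce to the stationary
distribution d_v/Σd and every vertex's score equals the global
degree-weighted assortativity coefficient — the property tests use this
as an independent oracle. A constant attribute (σ_e = 0) maps to the
all-zero field, consistent with reading 0 as uniform mixing.

### Personalized PageRank

The walk teleports back to the focal vertex with probability
`restart_probability` (default 0.15, the complement of the common 0.85
damping factor) and otherwise steps to a uniformly random neighbor.
Power iteration stops when the L1 residual falls below 1e−10 (10,000
iteration cap; non-convergence raises an error carrying the iteration
count and residual — reachable only for restart 0 on a periodic,
e.g. bipartite, graph). After convergence, weights below `weight_floor`
(default 1e−4) are truncated to zero and the vector renormalized; the
floor localizes the score to the focal neighborhood and is the exposed,
tunable form of a threshold whose original specification is not public.
Only this single scale is computed — no integration over restart
values — so the multiscale variant of the original local-assortativity
literature is out of scope.

`raw_local_assortativity` uses a batched power iteration that computes
all focal vertices' weight vectors in one matrix iteration (same fixed
point, same floor-and-renormalize); the unit tests assert row-by-row
equality with the single-vector operation. One weight matrix per cell
is shared across the whole panel.

## The bounded adjustment ϱ = h∘g∘f

Raw scores are not comparable across graphs. Three transforms fix this:

* **f (signed normalization)** — positives divided by the sum of
  positives, negatives by the sum of absolute negatives; zeros stay
  zero. When both signs occur the field sums to exactly 0 and each sign
  block totals ±1. All-zero fields are fixed points.
* **g (unit energy)** — division by the Euclidean norm √(Σ x̃²), i.e.
  a standardization with the mean pinned at zero rather than the sample
  standard deviation. The norm form is deliberate: it is what makes
  every component lie in [−1, 1], which the log step needs for its
  bound.
* **h (signed log)** — h(z) = sgn(z)·ln(|z|+1), strictly increasing and
  odd. The natural logarithm is used; the base only rescales all scores
  uniformly, and ln gives the closed-form bound.

Composing the three maps any raw field into [−ln 2, +ln 2]
componentwise: after g each |z_j| ≤ 1, and h(1) = ln 2. The bound is
property-tested on random vectors and on simulated cells.

## Filters

Two per-cell filters zero a marker before adjustment:

* **isotype threshold** — the maximum *total* count per cell among the
  isotype-control markers (totals, not per-node maxima, are used: the
  controls measure the cell-wide nonspecific binding level). A marker
  whose total is strictly below the threshold is zeroed; a marker tying
  the threshold is kept.
* **vertex threshold** — a marker must sit on strictly more than
  `vertex_threshold` (default 10) vertices.

Filtered fields are all-zero at stage "adjusted" and pass unchanged
through every downstream operation; their pairwise colocalization with
anything is exactly 0 by the zeroing rule.

## Colocalization

Pairwise scores are the Spearman correlation (average ranks on ties —
ties always exist because of zeroed vertices) of two adjusted fields
from the same cell. A printed formula in the source literature uses
uncentered rank products, which is not a correlation (reversed ranks
would not reach −1); this package implements the standard centered
Spearman that the method names, keeping scores in [−1, 1].

Higher-order scores select each marker's vertex set {v : ϱ_v > 0}
(strict inequality: uniform-mixing zeros are excluded; the threshold is
exposed for sensitivity analysis but fixed at 0 by default) and apply
the multiple-site similarity C_T = (T/(T−1))(1 − |∪A_i|/Σ|A_i|), which
is 0 when the sets carry no overlap and 1 iff all sets are equal and
non-empty, and reduces to Sørensen at T = 2. An all-empty family is
defined as 0.

Differential analysis compares per-cell scores between two samples:
mean difference, two-sided Wilcoxon rank-sum p-value, and the dot
category (0: p > 0.01; 1: 0.001 < p ≤ 0.01; 2: 0.0001 < p ≤ 0.001;
3: p ≤ 0.0001). The test is exact — full enumeration of all C(n₁+n₂,n₁)
rank assignments, handling ties through average ranks — whenever that
count is at most 200,000 (all group sizes up to 10 vs 10), and the
tie-corrected normal approximation otherwise; enumeration much beyond
that is not computable, and by ~20 observations per group the normal
approximation is standard practice. Two-sided p-values throughout;
sidedness is a convention here, as the contrasts are exploratory. No
multiple-testing correction is applied by default (dot categories are
raw-p conventions); a Benjamini–Hochberg column is available on the
differential table.

An optional permutation correction shuffles one marker's count vector
across vertices, recomputes the adjusted field per permutation, and
subtracts the per-node permutation mean from the observed field. Counts
(not ranks) are permuted; the filters are permutation-invariant, so a
filtered marker stays zero. The correction is seeded and reproducible
and is off (`n_perm = 0`) by default.

## Synthetic cells

The generator emulates MPX structure rather than MPX chemistry:

* A-pixels uniform on the unit sphere (a cell surface); each B-pixel
  attaches to the `mean_b_degree` (default 4) nearest A-pixels of a
  random anchor, giving a locally clustered, almost surely connected
  projection. Disconnected draws are retried up to 10 times.
* Marker molecules Poisson per A-pixel (the minimal count model),
  scattered uniformly over the pixel's incident edges.
* Polarized markers share one contiguous polar cap — the `cap_fraction`
  of A-pixels nearest a random pole — where the rate is multiplied by
  `enrichment_fold`, with the outside rate scaled down so the expected
  total is independent of the fold. This separates polarization from
  abundance by construction and is what the abundance non-confounding
  test leans on.
* Isotype controls are never polarized and use a low uniform rate.

Defaults: 300 A-pixels, 600 B-pixels, baseline rate 2.0 counts/A-pixel
(≈600 molecules per marker per cell, a realistic order for abundant
surface proteins at pixel resolution), isotype rate 0.05 (≈15 molecules,
well below specific markers), cap fraction 0.2 and fold 8 for stimulated
conditions. Population simulation derives independent per-cell seeds
from one master seed via `numpy.random.SeedSequence.spawn`.

What the generator does **not** emulate: pixel dropout, cell multiplets,
count saturation, marker–marker steric competition, or realistic panel
sizes (it ships an 11-marker panel, not ~80). Passing the recovery
tests therefore shows the scoring chain detects planted co-polarization
under idealized noise, not that it is robust to MPX artifacts.

## Study sizes and numerical conventions

The planted-signal study uses 40 cells per arm at 300 A-pixels — enough
for the rank-sum test to saturate its smallest attainable p-values while
keeping a full run around half a minute; the abundance study uses 30
cells per arm at 200 A-pixels. Convergence tolerance 1e−10 (L1),
weight-floor 1e−4, strict inequalities at both filter boundaries in the
directions stated above, and exact-zero conventions for degenerate
fields (constant attributes, all-zero inputs, undefined correlations)
are fixed package-wide.

## Known limitations

* The restart probability and weight floor parameterize a neighborhood
  scale the original method description leaves partially unspecified;
  conclusions at other scales require re-running with other values.
* Pairwise (correlation-based) and higher-order (set-overlap-based)
  scores are on different scales and must not be compared numerically.
* Adjusted scores are relative within a cell; absolute levels across
  panels or chemistries are not interpretable without a contrast.
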