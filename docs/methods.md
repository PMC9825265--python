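# Methods

This note documents the models and procedures implemented in `clonemorph`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic generators do and do not emulate.

## 2D morphology

Input is a 2D integer label image (0 = background) with an isotropic pixel
size in µm. Coordinates are (row, col), 0-based; physical position is
`index × pixel_size` at pixel centers. Labels are relabeled to consecutive
integers at ingest so arrays can be indexed by label and ordering is
deterministic.

Per cell: area = pixel count × pixel_size²; circumference = arc length of
the marching-squares boundary contour, subsampled every 3rd vertex before
summing segment lengths. The subsampling matters: the raw half-pixel
staircase overestimates a smooth boundary by ~6% (pushing a disc's
circularity to ≈0.89), while a Crofton 4-direction estimator is
asymptotically biased on polygonal outlines (a digital square converges to
circularity ≈0.88 instead of π/4). The subsampled contour keeps straight
edges exact and brings discs within ~2% of πd, so circularity behaves as
the definition 4πA/P² intends at both extremes. Circularity is clipped to
(0, 1]; aspect ratio is major/minor axis of the inertia-equivalent ellipse
(≥ 1, 1 for degenerate cells).

Cells whose bounding box touches the image border are flagged: truncated
outlines bias area/perimeter statistics, so they are excluded from
population summaries but retained as network nodes, where they still
occupy topology.

Population summaries per image: confluency (foreground fraction — the
density axis of the whole analysis), and per-property mean, population
variance (the image is the full observed population, not a sample), and
Shannon entropy H = −Σ p ln p in nats. Continuous properties are binned
with the Freedman–Diaconis rule, a scale-adaptive choice that avoids an
arbitrary fixed bin count; vertex degrees (below) use exact integer bins
because degree is discrete.

## Cell adjacency networks

Edge (u, v) iff the minimum Euclidean distance between boundary-pixel
centers of the two cells is strictly below the adjacency threshold
(default 5 µm; an exact-5 µm gap yields no edge). Candidate pairs are
pre-filtered by bounding-box separation and the exact minimum distance
found with a KD-tree over boundary pixels, so the result equals the
brute-force all-pairs computation (tested against it).

Metrics:

* degree mean / population variance / entropy (exact integer-degree bins);
* average colorability ⟨χ(G)⟩ = Σχ(cᵢ)/n over connected components.
  Chromatic numbers are exact for components up to `exact_limit` nodes
  (default 20): backtracking over increasing k starting from a greedy
  clique lower bound, with new-color symmetry breaking. Larger components
  fall back to a greedy largest-first upper bound and the result is
  flagged inexact (and a warning raised) — chromatic number is NP-hard,
  and honesty about the bound is preferable to silent approximation. Cell
  adjacency graphs are near-planar, so χ is small and the exact path
  almost always applies at these component sizes;
* component count, component-mass entropy H(|C|) over probabilities
  |cᵢ|/|G|, and the largest-component fraction |c₁|/|G|;
* box-counting fractal dimension of the rasterized cell foreground: the
  slope of log N(ε) vs log(1/ε) by least squares, grid anchored at the
  image origin. The box-counted set is the foreground mask (cell bodies):
  it is reproducible and directly expresses space-filling of the
  population. Default box sizes are powers of 2 from 2 px to min(shape)/4;
  box sizes are a parameter, and fixtures with ternary self-similarity
  (the Sierpinski carpet) are evaluated on powers of 3, where the cover
  counts are exact. At least 4 sizes spanning a decade are required.

## Segmentation evaluation

e_binary = |A_gt − A_pred|/A_gt over foreground areas and
e_object = |N_gt − N_pred|/N_gt over cell counts; undefined (missing) when
the denominator is zero. Both are scale-invariant. Duplicate predictions
from an instance segmenter are pruned by greedy non-maximum suppression on
mask IoU: masks visited in descending confidence (ties by input index),
dropped when IoU with any kept mask exceeds 0.5 (configurable). The
procedure is deterministic, idempotent, and order-independent for
distinct scores.

## Progressions and growth variables

Properties are fitted against confluency with a least-squares polynomial,
degree 2 by default (configurable): observed trends are smooth and
low-order, and a quadratic captures the rise-then-saturate/invert patterns
without overfitting small per-clone image counts. Residual variance is
SSR/(n−p). Fits require ≥ degree+1 distinct confluency values.

The growth-variable vector evaluates each property's fit at confluency
anchors 0.15 / 0.40 / 0.70 (suffixes `_l`, `_m`, `_h`) — a declared
convention spanning sparse, intermediate and near-confluent regimes.
Anchors outside a clone's observed confluency range are evaluated but
flagged as extrapolated; properties lacking fits yield flagged NaNs.
Growth variables are invariant to the time ordering of snapshots because
confluency, not acquisition time, is the regressor.

## Clustering

Variables are z-scored across clones (constant variables dropped with a
warning; variables with ≤10% missing entries median-imputed, worse ones
dropped rather than silently filled), then Ward linkage on Euclidean
distance — the standard choice for compact morphological classes, and
configurable. Flat labels come from a maxclust cut. The two-stage
procedure cuts all clones into 2 superclasses, then each superclass into
3 subclasses; when known line identities are provided, stage-1 agreement
is reported as best-matching accuracy. A UMAP embedding (seeded, hence
deterministic) is provided purely as a visual check; nothing quantitative
depends on it.

## Spheroid invasion

A 75 µm window of slices (15 at the 5 µm default spacing; each slice
counts as one spacing increment) is selected around the slice with maximal
provisional foreground — a deterministic operationalization of "the middle
of the spheroid" — and max-projected. Binarization is global Otsu
(fixed-threshold override available), followed by removal of components
below `min_area` (default 50 µm²) and hole-filling within the main body.

The main body is the largest connected component: area, circularity
(4πA/P², same contour perimeter as in 2D), solidity (A / convex hull
area). Protrusions: the body is opened with a disc of `core_radius`
(default 0.8 × the body's equivalent radius; auto-shrunk if the opening
would vanish). Residue components touching the core are protrusion
candidates; a candidate counts when its radial extent — tip distance to
the spheroid centroid minus the core's own maximal radial reach — is at
least `min_protrusion_length` (default 20 µm), which suppresses raster
fringe. The recorded length is the tip-to-centroid distance. The centroid
is taken from the opened core rather than the full body: asymmetric
protrusions would otherwise displace the very reference point they are
measured against. Disseminated regions are the remaining components with
area ≥ `min_area`; their distance is centroid-to-centroid against the full
main body's centroid.

invasion3D: replicate spheroids are averaged per clone and metric first;
each of n_p, avg_p, max_p, n_c, avg_c, max_c is then min–max normalized
across the clone panel (a metric constant across clones normalizes to 0,
with a warning) and the six normalized values averaged. The score is
invariant to positive affine rescaling applied uniformly to any one
metric, and requires at least two clones.

## Correlations

Spearman rank correlations (mid-rank ties, pairwise-complete observations
— appropriate for small clone panels) over a clones × variables table; 2D
variables enter at the mid-density anchor by default so each clone
contributes one value per variable. Correlation graphs add an edge for
every off-diagonal pair with |r| strictly above the threshold (0.8 for the
variable–variable graphs) with sign and |r| as attributes; the invasion
star keeps only edges incident to invasion3D at threshold 0.3, leaving 2D–
2D relations undrawn. Edges are thresholded on |r|, not on p-values, so no
multiple-testing correction is applied; p-values are not used for edges.

## Synthetic generators

All generators are deterministic given their integer seed.

**Populations.** Cells are perturbed ellipses (2nd–4th harmonic radial
perturbation, default relative amplitude 0.08) sampled as 128-vertex
polygons in continuous µm coordinates and placed by rejection sampling.
Ground-truth areas, centroids and pairwise boundary gaps are polygon
quantities (shapely), exact by construction; planted adjacency is gap
< 5 µm. Two safeguards keep that truth unambiguous after rasterization:
placements with a nearest gap inside the exclusion band (3.5–7 µm around
the threshold) are rejected, and — because raster boundary distances can
only inflate a continuous gap (pixel centers lie strictly inside the
outlines) — any placement whose raster classification would disagree with
its continuous one is rejected too. Defaults (semi-axes 8–20 µm at
1 µm/px, min gap 2 µm, up to ~30% confluency on 384–512 px fields,
roughly 60–200 cells) represent a moderately dense epithelial-like field
at desk-scale problem sizes. The generator does not emulate image noise,
segmentation errors, cell division or motility — tests passing on it
demonstrate the correctness of the measurement and graph machinery, not
robustness to segmentation failure (that is what `segeval` is for).

**Progressions.** Per-property quadratic trends plus i.i.d. Gaussian noise
on a confluency grid, returning the planted coefficients.

**Spheroids.** A disc body (default radius 100–120 µm) with capsule arms
whose rounded tips end exactly at the planted tip-to-centroid distance,
and disc blobs of planted area at planted centroid distances, placed on an
interleaved angular grid. Since asymmetric arms shift the connected body's
raster centroid, blob distances are planted from that actual centroid —
the same reference the measurement uses. The middle slice carries the full
cross-section; flanking slices carry sphere-profile discs, so the central
max projection recovers the planted mask exactly. Intensities are
foreground 200 / background 20 with Gaussian noise (default sd 6,
SNR ≈ 30); 15 slices at 5 µm; 320–384 px fields at 2 µm/px. Real confocal
artifacts (attenuation with depth, anisotropic PSF, touching spheroids)
are not modeled.

**Clone panels.** Nested planted partition: superclass and subclass
centers along random unit directions with between-group separation ≥ 4×
the within-group sd, 60 clones × 8 variables by default — the regime where
hierarchical clustering should recover the planted hierarchy exactly, used
to validate the clustering stack end to end.

## Degenerate inputs and tie-breaking

Empty networks raise on statistics that are undefined for them; edgeless
graphs return (0, 0, 0) degree statistics; single-pixel cells fall back to
their own pixel as boundary; perimeter is floored at one pixel; NMS ties
break on input index; duplicate clone vectors merge at height 0 and a cut
that cannot produce k distinct clusters raises rather than relabeling
silently.

## Known limitations

* Chromatic numbers above `exact_limit` are greedy upper bounds (flagged).
* The contour perimeter retains a small (<~2%) resolution-dependent bias;
  circularity comparisons should use a consistent pixel size.
* Growth-variable anchors assume clones were imaged across a confluency
  range covering ~0.15–0.70; outside it values are extrapolations of a
  quadratic and flagged as such.
* invasion3D is a relative score: it is only comparable within the clone
  panel it was normalized on.
* The pipeline consumes segmentations; it does not correct them.
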