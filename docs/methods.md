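# Methods notes

## Scope and model

`glandnet` measures the local coherence of gland orientations in annotated
histology regions.  The core object is the *gland network*: a connected
component of a sparsified graph over gland centroids.  Within each network
the pairwise co-occurrence of discretized gland angles is accumulated into a
symmetric B×B matrix, and second-order statistics of that matrix quantify
orientation disorder.  The modeling assumptions are:

- glands are bright, roughly convex blobs in the CIELAB L* channel,
  separable from stroma by intensity contrast alone;
- a gland's orientation is meaningful only as an axis (mod 180°), so all
  angular statistics are axial;
- disorder is a *local* property: only glands that are path-connected in
  the subgraph co-occur, so stroma-separated gland clusters never mix.

## Segmentation

Seeds are regional maxima of the Gaussian-smoothed luminance restricted to
the annotation mask.  A maximal equal-value plateau yields one seed at its
centroid; plateaus without a strictly lower neighbour (flat areas) yield
none.  Defaults: smoothing scales σ ∈ {10, 20, 40} px at 0.5 μm/px, chosen
to cover small-to-large acini at 20× magnification; the growth bounding box
is 8σ so it exceeds any plausible gland diameter at that scale; regions
under 30 px are discarded as specks.

Region growing absorbs the brightest current-boundary pixel each iteration
(ties: earliest raster order) and stops when the brightest candidate lies
outside the bounding box.  Boundary strength is mean(IB) − mean(CB); the
snapshot of maximal strength (earliest on ties) is returned.  The loop
maintains IB incrementally, which is algebraically identical to recomputing
"region pixels adjacent to CB" each iteration but O(1) per step; the
compiled (numba) loop and a pure-Python mirror implement the same contract
and are cross-checked in the tests.  Pixels outside the annotation mask are
treated as unavailable (never enter CR or CB), so glands crossing the
annotation boundary are clipped to it.  Overlap resolution repeatedly
removes the overlapping region of lowest strength (ties: the later-seeded
region), which is order-equivalent to scanning candidates in ascending
strength.

Known behaviour: the method has no background-region filter, so a regional
maximum of smoothed noise inside a gland-free part of the annotation grows
a low-strength region that survives if it overlaps nothing.  Real
annotations (and the phantom's default mask) outline glandular tissue, which
keeps such maxima rare; analyses of masks containing large empty stroma
should expect occasional spurious low-strength segments.

## Orientation estimation

The orientation is the leading eigenvector of the covariance of boundary
points.  Contours extracted by marching squares place vertices at pixel-grid
crossings, so vertex density depends on local edge direction; PCA on the raw
vertices is biased by up to ~2.7° for 30/12 px ellipses.  Boundaries are
therefore resampled to 256 points uniformly spaced by arc length before PCA,
reducing the worst-case error to ~1.2° (still boundary points only, not the
filled region).  Angles are reported in [0°, 180°) as atan2(v_y, v_x) mod
180 on the (x = column, y = row) components; because rows grow downward this
is mirrored relative to on-screen counterclockwise, which is immaterial for
axial-disorder statistics as every module (including the phantom renderer)
shares the convention.  Near-circular glands (eigenvalue ratio > 0.95) keep
their numerically returned axis and are flagged by low eccentricity rather
than excluded.

## Gland graph

Edge rule: connect i, j when w = d(i,j)^(−α) exceeds r, with centroid
distance in pixels clamped below at 1 px.  Defaults α = 0.5, r = 0.1
connect glands within 100 px (50 μm at 0.5 μm/px), a reach of roughly one
gland diameter at the default phantom geometry.  A `sampled` mode draws each
edge as a Bernoulli(w) trial under a mandatory seed, matching the
probabilistic cell-graph literature the rule comes from; the deterministic
threshold is the default for reproducibility.  `parameter_grid` exposes an
(α, r) grid for re-tuning by cross-validation on new data.

## Angularity features

Angles are binned by floor(θ/ω) with ω = 10° (B = 18).  Each network with at
least two members contributes one symmetric count matrix (each unordered
pair increments two symmetric cells; self-pairs are not counted).  The 13
statistics use the fixed conventions: contrast family on the |a−b| diagonal
distribution, intensity family on the a+b distribution,
entropy/energy/correlation on the joint distribution, information measures
in the HXY1/HXY2 forms; logs base 2 with 0·log 0 = 0; correlation is defined
as 0 when a marginal variance vanishes (single-bin networks).  Aggregation
across networks uses the sample (n−1) standard deviation, with std = range =
0 for a single network; a region with no usable network returns a zero
vector flagged by `n_neighborhoods_used = 0` and a warning.

## Comparator families

- *Morphology* (100): 25 per-gland descriptors × {mean, std, median,
  min/max}.  The descriptor list contains one duplicate name in its source
  table; it is implemented once (distance ratio = mean/max centroid-to-
  boundary distance) and the list is padded with the variance of the raw
  (unnormalized) radial distances to preserve the 100-feature total.  Hu
  moments are computed on the filled pixel set, fractal dimension by
  box-counting over dyadic scales, Fourier descriptors as the first 10
  non-DC magnitudes of the radial series normalized by the DC term.
- *Voronoi* (12): cells clipped to the centroid bounding box so all are
  finite and partition the window; chord = longest vertex-to-vertex
  distance.
- *Delaunay* (8): per-triangle side lengths (3 per triangle, shared sides
  counted per triangle) and areas.
- *MST* (4): Euclidean minimum-spanning-tree edge lengths.
- *Density* (24): neighbour counts within 10–50 px (≤ radius, self
  excluded) and 3rd/5th/7th nearest-neighbour distances.
- *Texture* (26): symmetric 256-level co-occurrence at distance 1 in the 4
  unique directions, restricted to pixel pairs inside the mask; L* is
  quantized to 8 bits; the 13 statistics are averaged (mean, std) over
  directions.

Aggregates for these families use the population (n) standard deviation so
single-structure inputs are naturally zero-spread; the angularity family
keeps the sample convention above.  "Disorder" is 1 − 1/(1 + σ/μ) ∈ [0, 1),
defined as 0 when the mean is 0.  Min/max ratios are min/max, with 1 for
constant values.

## Evaluation harness

Random forest (100 trees), per-case decision score 2v − 1 from the positive
vote fraction v.  Repeated cross-validation draws, per repeat, a fresh
stratified 3-fold split (stratification keeps both classes in every training
fold at 40-case scale — a documented choice where plain random splitting
would occasionally produce single-class folds); the pooled held-out
predictions of a repeat give one accuracy and one AUC, and summary spread is
across repeats.  AUC uses the rank (Mann–Whitney) formulation, equivalent to
trapezoidal integration of the threshold-swept ROC with tie plateaus.
Kaplan–Meier and logrank come from lifelines, cross-checked in the tests
against hand tabulations.

## Synthetic phantoms

Phantoms emulate annotated regions: ellipses (default semi-axes 30/12 px
± 20% jitter) at L* ≈ 85 on L* ≈ 45 stroma, pixel noise σ = 3 L*, ≥ 70 px
center spacing, 25 glands in 512×512 px.  These values make the default
segmentation succeed while keeping the contrast (≈ 40 L* against σ = 3
noise) far from photometric realism.  Orientations come from a wrapped von
Mises on the half-circle (doubled-angle construction); κ = 0 is uniform
disorder.  The annotation mask is the union of glands dilated by 15 px,
emulating an annotation that excludes gland-free stroma.  Images are
composed in L* and converted to neutral-gray 8-bit RGB via the inverse
sRGB↔L* mapping, so 8-bit quantization perturbs the luminance by ≲ 0.25 L*.
Cohorts pair aligned (κ = 32, "NR"-like) and disordered (κ = 0, "BCR"-like)
cases with exponential survival (hazards 0.004 vs 0.03 per month — median
recurrence ≈ 23 months for the aggressive class) and independent uniform
censoring on [0, 120] months.

What the phantoms do **not** model: H&E color and stain variation, lumen and
nuclear substructure, touching or lobulated glands, annotation errors, and
intensity overlap between glands and stroma.  Passing recovery tests on
phantoms therefore demonstrates the correctness of the algorithmic chain,
not clinical segmentation performance.

## Problem sizes

The test suite and acceptance script size their simulations for a single
CPU: 10 default phantoms for segmentation recovery, a 5-level κ grid × 20
layouts for disorder monotonicity, a 40-case layout cohort with 10 CV
repeats (the evaluation harness itself supports the conventional 100), and
20 random instances per brute-force oracle comparison.

## Known limitations

- Boundary strength compares raw L* means; no normalization for stain or
  illumination variation is attempted (out of scope, as is whole-slide I/O).
- Exact gland-count recovery assumes the annotation excludes large
  gland-free areas (see Segmentation above).
- The graph defaults (α, r, ω) were fixed a priori from geometry arguments;
  on real cohorts they should be re-tuned via `parameter_grid` and
  cross-validation.
- Delaunay features require centroids in general position; collinear
  layouts raise an error rather than degrade silently.
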