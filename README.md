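# glandnet

Gland-network architecture features for digitized prostate histopathology.

In benign and indolent prostate tissue, glands tend to align with the
surrounding fibromuscular stroma, so neighbouring glands share a common
orientation; in aggressive disease that local coherence breaks down.
`glandnet` quantifies this with the **co-occurring gland angularity (CGA)**
feature family: glands are segmented, each gland's orientation θ ∈ [0°, 180°)
is estimated from its boundary, glands are linked into local networks, and
the disorder of orientations within each network is summarized by
second-order statistics of an angular co-occurrence matrix.  The package is
aimed at quantitative-histomorphometry researchers studying biochemical
recurrence (BCR) after radical prostatectomy and related outcome-prediction
problems.

## Method

Given an annotated RGB region at known resolution (default 0.5 μm/px):

1. **Segmentation** — glands appear as bright blobs in the CIELAB luminance
   channel L*.  Seeds are regional maxima of Gaussian-smoothed L* at several
   scales; from each seed a region grows inside a k×k box by repeatedly
   absorbing the brightest current-boundary (CB) pixel.  The *boundary
   strength* — mean(IB) − mean(CB), with IB the region pixels adjacent to
   CB — is tracked every iteration, and the contour of maximal strength is
   kept.  Overlaps are resolved by discarding the weaker region.
2. **Orientation** — each gland's angle θ is the direction of the first
   principal component of its boundary points (undirected, mod 180°).
3. **Local subgraphs** — gland centroids i, j are connected when the
   decaying weight d(i,j)^(−α) exceeds a threshold r (defaults α = 0.5,
   r = 0.1 ≈ 100 px reach).  Connected components are the *gland networks*.
4. **Angular co-occurrence** — angles are binned at ω = 10° (B = 18 bins);
   for each network, the symmetric B×B matrix M counts the binned angle
   pairs of all gland pairs.  Thirteen Haralick-style statistics (entropy,
   energy, correlation, contrast/intensity families, two information
   measures) describe each M; their mean, standard deviation and range
   across networks give the 39-element CGA region descriptor.
5. **Evaluation harness** — random-forest classification with repeated
   randomized stratified 3-fold cross-validation (accuracy, ROC/AUC), plus
   Kaplan–Meier curves and the logrank test on predicted groups.

Six comparator feature families (gland morphology 100, Voronoi 12, Delaunay
8, minimum spanning tree 4, gland density 24, intensity co-occurrence
texture 26) are provided for benchmarking, and a synthetic-phantom module
renders ground-truthed regions of elliptical glands whose orientation
disorder is controlled by a wrapped von Mises concentration κ (κ → ∞
aligned, κ = 0 uniform).

## Worked example

```python
import glandnet as gn
from glandnet.pipeline import cga_features_from_image

spec = gn.PhantomSpec(orientation_kappa=32.0, seed=3)   # well-aligned glands
img, truth = gn.generate_phantom(spec)
vec, glands = cga_features_from_image(img)
print(f"segmented {len(glands)} glands, {vec.n_neighborhoods_used} gland networks")
for name in ("cga_entropy_mean", "cga_energy_mean", "cga_contrast_average_mean"):
    print(f"{name:30s} {vec.values[name]:.4f}")
```

prints

```
segmented 25 glands, 1 gland networks
cga_entropy_mean               2.5250
cga_energy_mean                0.2355
cga_contrast_average_mean      0.5929
```

All 25 glands of the phantom are recovered and fall in one connected
network.  Because the glands are well aligned (κ = 32), the co-occurrence
counts concentrate in few bins: entropy is low and energy high.  Rerunning
with `orientation_kappa=0.0` (fully disordered orientations) raises
`cga_entropy_mean` to 6.4267 — the separation the downstream classifier
exploits.

The same pipeline is available from the shell:

```sh
glandnet phantom --seed 1 --out-dir ph/
glandnet segment --image ph/phantom.png --mask ph/mask.png --out polygons.csv
glandnet features --polygons polygons.csv --omega 10 --out features.csv
glandnet classify --features features.csv --labels labels.csv --out cv.json
glandnet survival --records survival.csv --out km.json
```

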