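# Methods

This note documents the models and conventions behind `gliamorph`, the
parameters that matter, what the synthetic phantoms do and do not
emulate, and the numerical choices made where the design was open.

## Segmentation

**Thresholding.** A single Otsu threshold is computed per stack over the
full-stack histogram (never pooled across a cohort): the level *t*
maximizing the between-class variance σ²_b(t) = w₀w₁(μ₀−μ₁)², with
foreground defined *strictly above* *t*. The argmax scan runs in exact
integer arithmetic — σ²_b is proportional to (m₀W − Mw₀)²/(w₀w₁), a
ratio of integers for an integer histogram — so ties resolve to the
lowest threshold deterministically; float round-off cannot flip
near-tied candidates. A constant image raises a degenerate-histogram
error.

**Otsu's operating regime and the optional pre-filter.** Between-class
variance maximization needs the foreground class to carry histogram
weight of at least roughly (σ_noise/Δμ)², where Δμ is the
background-to-signal contrast. In a sparse field (a single ramified cell
occupies well under 1 % of its bounding volume) and at contrast-to-noise
5, the threshold collapses into the background mode. `segmentation`
therefore offers a Gaussian pre-filter (`denoise_sigma_um`, σ given in
µm and converted per axis). It is **off by default** — intensities are
otherwise treated as raw counts and the native histogram is used — and
is enabled explicitly in noisy studies (the verification studies use
0.375 µm at 0.5 µm voxels). This plays the role deconvolution plays for
high-background confocal stacks.

**Object filtering.** Connected components are labeled under
configurable connectivity (default 26, so thin diagonal processes do not
fragment; 6 and 18 available). The user-sized noise filter removes
components below `min_object_voxels`. The size gate is calibrated from
two reference cells the analyst names (largest single cell, smallest
complete cell) — or directly as voxel counts in the config, so batch
runs need no interaction; objects strictly larger than the largest
single cell are presumed merged reconstructions (`too_large`), strictly
smaller ones debris (`too_small`). A ranked object-size table is
printed to stand in for the interactive pick-a-cell step.

**Completeness.** A cell is incomplete when less than `interior_min`
(default 0.8) of its voxels lie off the six faces of the stack. Soma and
process voxels are weighted equally — each voxel counts once — because
the criterion is not voxel-precise in any sharper sense. Manual
overrides win over both filters and every exclusion is recorded with its
reason, so the audit trail is reportable.

## Morphometry

**Volumes.** Cell volume is voxel count × dz·dy·dx. Territory is the
volume of the 3D convex hull of the cell's *voxel centers* in physical
coordinates (the simplest well-defined convention; the ≈half-voxel
shrinkage is symmetric across groups). The ramification index is
territory / volume. For thin cells whose center hull is smaller than the
voxel volume, territory is clamped to the cell volume and flagged
(`degenerate_territory`), so RI is never silently below 1; coplanar or
collinear cells degrade the same way.

**Skeletons.** Each cell mask is thinned on the voxel lattice
(topology-preserving 3D thinning); no isotropic resampling, since
resampling changes topology unpredictably. The skeleton voxels form a
graph under 26-adjacency with physical step lengths, cleaned in three
standard ways:

* within every 3-clique of mutually adjacent skeleton voxels the longest
  edge is dropped (staircase turns otherwise masquerade as junctions;
  removing one triangle edge can never disconnect the graph);
* branching voxels (degree ≥ 3) that are adjacent, or bridged by a
  single intervening chain voxel, are merged into one junction —
  thinning renders one anatomical bifurcation as a small cluster, and
  junctions under one voxel apart are not anatomically distinct;
* spur branches from an endpoint to a junction shorter than
  `prune_length_um` (default 2 µm) are removed iteratively; they are
  thinning artifacts that inflate endpoint counts. Free-standing
  segments are never pruned.

Branchpoints are junction clusters; endpoints are degree-1 voxels; a
branch is the path between consecutive critical nodes. Branch length is
the physical length of the path after a 3-point moving average of the
coordinates (ends fixed): plain voxel-step sums overestimate oblique
runs by up to ~8 %, and the light smoothing centers the error near zero
without shortening straight runs. A skeleton reduced to ≤ 1 voxel, or an
unbranched remnant shorter than the prune length (e.g. the skeleton of a
ball), is flagged `degenerate_skeleton` and reported with zero counts
and lengths — zeros are always explicit and filterable, never silent.

**Soma.** The soma center is the voxel maximizing the Euclidean distance
transform of the cell mask (anisotropic sampling; ties to the lowest
(z, y, x)). The soma body is the connected component, containing that
center, of cell voxels whose distance value is ≥ `soma_fraction`
(default 0.5) of the maximum. The soma centroid is also the Sholl
center.

**Sholl.** For radii r = step, 2·step, … ≤ max_radius, the profile
counts skeleton *edges* straddling the sphere of radius r about the
center (endpoint distances d_lo < r ≤ d_hi), in physical units. Spheres
intersect the skeleton, not the raw mask — the standard 3D definition.

**Expected accuracy** (measured by the verification studies, not
asserted beyond them): on noise-free phantoms branchpoint/endpoint
counts match the generated topology exactly in ≈ 99.7 % of phantoms
(the residue is forks whose children merge at voxel scale); branch
lengths match ground truth to a few tenths of a µm typically, with a
small negative bias from tip erosion during thinning, and individual
soma-adjacent or inter-junction branches occasionally deviate by up to
~2.5 µm when a junction settles away from the geometric joint. At
contrast-to-noise 5 (with the pre-filter) counts stay within ±1 and
matched branch lengths move by well under two voxel diagonals relative
to the noise-free measurement.

## Clustering

The order is fixed: pooled Z-score, PCA, UMAP, then K-means.

* **Z-score** uses the pooled mean and *sample* SD (n−1) over all cells,
  never per group; σ = 0 columns become 0 and are reported. Rows with
  missing parameters (the expected source is degenerate-skeleton rows
  exported as blanks) are dropped with a logged count.
* **PCA** is the eigen decomposition of the covariance of the
  standardized matrix (= the correlation matrix). Components are sorted
  by decreasing eigenvalue; variance percentages are relative to the
  total over all eigenvalues, so the full set sums to 100. Sign
  convention: the largest-magnitude loading of each component is
  positive. All components feed UMAP by default (`n_components`
  configurable) — no arbitrary variance cutoff.
* **UMAP** (n_neighbors 15, min_dist 0.1, fixed seed echoed into the run
  metadata) is a contract-level dependency: deterministic per seed and
  preserving coarse neighbor structure. K-means (best of `n_init`
  initializations) runs on the 2D embedding by default; clustering on
  PC scores directly is available (`cluster_space: pca`) for sensitivity
  analysis.
* **k defaults to 3** — the three canonical morphologies (amoeboid /
  intermediate / ramified) — but is a config parameter; nothing in the
  method fixes it, so an exploratory silhouette scan over k is the
  recommended check when the population structure is unknown.
* **Cluster ids are relabeled** in ascending cluster-mean PC1. Since all
  eight parameters load positively on PC1 in practice, cluster 1 is the
  most amoeboid and cluster k the most ramified, stable across seeds.
* **Statistics.** Group × cluster frequencies get a Pearson chi-square
  (df = (r−1)(c−1), expected counts reported, cells with expectation
  < 5 flagged). Per parameter, a D'Agostino–Pearson test on the pooled
  values gates the comparison: consistent with normality → one-way ANOVA
  with Bonferroni-adjusted pairwise t-tests; otherwise → Kruskal–Wallis
  with Dunn's rank-based z comparisons (tie-corrected, Bonferroni
  adjusted). Parameters with any cluster below 3 cells, or constant
  data, are flagged and not tested.

## Two-group report

Morphological parameters across cell populations are generally
non-normal, so the two-group comparison is the two-sided Mann–Whitney U
(exact for small samples without ties, asymptotic with tie correction
otherwise), corroborated by the two-sample KS test. The effect size is
r = Z/√N with Z the tie-corrected normal approximation — one of several
conventions in use; it is recorded in the output metadata. The median
difference is the Hodges–Lehmann estimate with the distribution-free
95 % CI from the k-th order statistics of all pairwise differences.
Analyses run at the individual-cell level, which inflates the apparent
sample size; every comparison carries that caveat verbatim and the run
report prints per-animal cell counts. Mixed-effects modeling of Sholl
curves is deliberately out of scope; the long-format Sholl table is
exported for use in dedicated mixed-model software.

## Synthetic phantoms

**Image phantoms** emulate IBA-1-filled cells: a soma ball (radius
2.4–3 µm by archetype) plus a random tree of capsule segments (cylinder
+ hemispherical caps, radius 1–1.2 µm). Growth is tip-based: primaries
leave the soma center in evenly spread, randomly rotated directions and
run one soma radius plus a drawn segment length; at each joint below the
maximum depth the tip bifurcates with probability `bifurcation_prob`
(children split ±40–57° about the parent direction) or continues with a
tortuosity-perturbed direction. Segment lengths are N(5.5, ~0.6) µm
clipped to [4.8, mean+2.5σ]: the lower clip keeps every terminal branch
above the 2 µm prune length even after the ~2.5 µm junction-side erosion
that thinning produces, so the rendered topology is recoverable by
construction. A collision guard keeps non-adjacent capsules at
≥ 2·branch_radius + 2 µm (two voxel diagonals at the reference 0.5 µm
isotropic spacing), so distinct branches never fuse when voxelized; a
segment that cannot be placed is dropped and the recorded ground truth
follows the tree actually built. Depth limits are ≤ 1 (amoeboid), 2
(intermediate), ≥ 3 (ramified). Intensities are background 100 +
contrast 200 on foreground + optional additive Gaussian noise
(contrast-to-noise 5 ⇒ noise SD 40), quantized to uint16. Capsule
rendering gives analytic volume checks (soma ball + out-of-soma cylinder
parts + leaf caps).

What the phantoms do **not** emulate: PSF blur (available as an optional
flag, off by default), photon (Poisson) noise, depth attenuation,
anisotropic optics, touching or interdigitating cells, and uneven
background. Passing the phantom studies therefore demonstrates the
correctness of the measurement chain on resolvable geometry, not
segmentation performance on hard real tissue; the size gate's
merged-cell path is exercised by dedicated fixtures rather than random
collisions.

**Feature tables** draw the eight parameters per cell from per-archetype
diagonal Gaussians whose means are separated by ≥ 2 pooled SD on most
parameters (defaults in `FEATURE_ARCHETYPE_MEANS`/`_SDS`, chosen to
match the scale of per-cell morphometrics tables: volumes in the
hundreds of µm³, RI 1.8–8.5, a handful to a dozen branchpoints). The
treatment contrast shifts only the archetype *mixing proportions*
between groups — P(ATP | archetype) = (0.5+s, 0.5, 0.5−s) — never the
parameter values, emulating a redistribution of cells across
subpopulations. The default study size is 240 cells (80 per archetype),
matching the scale of a two-group, ~4-animals-per-group cell-level
dataset.

**Statistical design facts** (computed by the verification studies): the
chi-square frequency test on a VEH(⅓,⅓,⅓) vs ATP(0.5, 0.3, 0.2),
120-cells-per-group design has noncentrality λ ≈ 8.2 (df 2), i.e.
theoretical power ≈ 73 % at α = 0.05 — reaching 80 % would need ≈ 140
cells per group. Its type-I error is nominal (within [0.03, 0.07] over
500 null simulations). End-to-end cluster recovery on the default
three-archetype table reaches median ARI ≥ 0.9 over 20 seeds (in
practice 1.0).

## Numerical and degenerate-input conventions

* Axis order is (z, y, x) everywhere; spacing (dz, dy, dx) in µm comes
  from the config, never from TIFF tags.
* Otsu ties → lowest threshold; threshold equality is *strict* for
  foreground membership.
* Distance-transform ties for the soma center → lowest (z, y, x).
* Sholl sphere membership: an edge crosses radius r iff
  d_lo < r ≤ d_hi.
* Hull failures (coplanar, collinear, < 4 points) → territory = cell
  volume, flagged; RI = 1.
* K-means relabeling uses a stable argsort, so equal cluster means
  cannot swap ids between runs.
* All randomness flows through explicit integer seeds; re-running any
  stage with the same inputs and seeds is byte-identical.

## Known limitations

* Touching cells are not split (no watershed); the size gate is the only
  merged-cell defense, as in the semi-automated workflow it mirrors.
* Branch lengths carry a small negative bias from tip erosion during
  thinning, and junction positions can settle ~1 voxel away from the
  geometric joint; per-branch errors beyond two voxel diagonals occur at
  the ~10⁻³ level on resolvable phantoms.
* Global Otsu assumes a usable bimodal histogram; very sparse or very
  noisy fields need the pre-filter (or a crop to the region of
  interest).
* UMAP is used as a contracted dependency; only its determinism and
  coarse neighbor-structure preservation are relied upon, and K-means on
  the embedding inherits UMAP's distortions (the PC-space mode exists
  for exactly that reason).
* Cell-level statistics overstate significance under pseudoreplication;
  the report surfaces per-animal counts but does not fit nested models.
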