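# gliamorph

3D morphometry of microglia from confocal z-stacks, with downstream
morphological subpopulation analysis.

Microglia — the resident immune cells of the CNS — shift between a
*ramified* state (small soma, many long branching processes) and an
*amoeboid* state (compact, few branches) as they react to injury,
stress, or pharmacological challenge (e.g. ATP). Quantifying that shift
from IBA-1–stained tissue is a standard readout in neuroimmunology, but
it requires a reproducible chain from raw z-stack to per-cell numbers.
`gliamorph` implements that chain end to end, for researchers who want
scriptable, seed-deterministic batch analysis rather than interactive
GUI workflows:

1. **Segmentation** — a global Otsu threshold *t* maximizing the
   between-class variance σ²_b(t) = w₀w₁(μ₀ − μ₁)² of the stack
   histogram (exact integer arithmetic, lowest tie), a user-sized noise
   filter on connected components, a size gate calibrated on the largest
   single / smallest complete cell (removing debris and merged
   reconstructions), and a completeness criterion excluding cells with
   less than 80 % of their voxels away from the stack faces.
2. **Morphometry** — topology-preserving 3D thinning of each cell mask,
   then the eight standard parameters per cell: cell volume *V*,
   territory *T* (convex-hull volume), ramification index RI = *T*/*V*,
   branchpoint and endpoint counts, and average/min/max branch length;
   plus a distance-transform soma volume and a 3D Sholl profile
   (skeleton crossings of concentric spheres about the soma). All
   lengths and volumes are in µm using the physical voxel spacing
   (anisotropic stacks supported without resampling).
3. **Clustering** — pooled Z-score *z* = (*x* − μ)/σ, PCA (eigen
   decomposition of the correlation matrix), 2D UMAP embedding, K-means
   (default k = 3), a Pearson chi-square on the group × cluster
   frequency table, and per-parameter cluster comparisons gated by a
   D'Agostino–Pearson normality test (ANOVA + Bonferroni, or
   Kruskal–Wallis + Dunn).
4. **Reporting** — two-group Mann–Whitney U (effect size r = Z/√N,
   Hodges–Lehmann 95 % CI on the median difference) and
   Kolmogorov–Smirnov comparisons, with per-animal cell counts printed
   so cell-level pseudoreplication stays visible.
5. **Synthetic phantoms** — cells rendered as a soma ball plus a random
   tree of capsule segments with exact recorded topology, and tabular
   archetype mixtures with hidden labels, so every stage is verifiable
   without any data download.

## Worked example

```python
from gliamorph import synthetic, segmentation as seg, morphometry as mm
from gliamorph.config import PipelineConfig
from gliamorph.clustering import cluster_pipeline, frequency_test

cfg = PipelineConfig(spacing=(0.5, 0.5, 0.5), denoise_sigma_um=0.375)

# render three intermediate-morphology phantoms into one noisy stack
specs = [synthetic.default_spec("intermediate", seed=s, noise_sd=20.0) for s in (1, 2, 3)]
grid, truths, _ = synthetic.generate_phantom_stack(specs, (90, 180, 180), cfg.spacing, placement_seed=4)

smoothed = seg.smooth_stack(grid, cfg.denoise_sigma_um)
threshold = seg.otsu_threshold(smoothed)
label_map = seg.binarize(smoothed, threshold, cfg.min_object_voxels, cfg.connectivity)
cells = seg.select_cells(label_map, interior_min=cfg.interior_min)
records = mm.measure_cells(cells, grid.shape, cfg)

print(f"Otsu threshold: {threshold}; cells segmented: {len(records)}")
for r, t in zip(records, truths):
    print(f"cell {r.cell_id}: volume {r.cell_volume_um3:.0f} um3, RI {r.ramification_index:.2f}, "
          f"branchpoints {r.branchpoints} (truth {t.branchpoints}), endpoints {r.endpoints} (truth {t.endpoints})")

# subpopulation analysis of a 240-cell table whose ATP group is shifted
# toward amoeboid *composition* (parameter values untouched)
table, _ = synthetic.generate_feature_table((80, 80, 80), group_shift=0.25, seed=9)
result = cluster_pipeline(table, PipelineConfig(k=3, seed=17))
print(f"PC1+PC2 variance: {result.variance_explained[:2].sum():.2f}%")
print(result.frequency_table)
ft = frequency_test(result.labels, result.meta["group"])
print(f"chi2 = {ft['chi2']:.2f}, df = {ft['df']}, p = {ft['p']:.2e}")
```

Output:

```
Otsu threshold: 176; cells segmented: 3
cell 1: volume 276 um3, RI 8.14, branchpoints 4 (truth 3), endpoints 6 (truth 5)
cell 2: volume 289 um3, RI 8.39, branchpoints 4 (truth 4), endpoints 6 (truth 6)
cell 3: volume 258 um3, RI 6.42, branchpoints 3 (truth 4), endpoints 5 (truth 6)
PC1+PC2 variance: 87.47%
cluster   1   2   3
group              
ATP      62  38  22
VEH      18  42  58
chi2 = 40.54, df = 2, p = 1.57e-09
```

Reading it: at this noise level (SNR 10) the recovered branch topology is
within ±1 of the generator's ground truth for every cell. In the tabular
study, cluster 1 collects the amoeboid-like cells (lowest PC1), cluster 3
the ramified ones; the ATP group is over-represented in cluster 1 and
depleted in cluster 3 while the per-cluster parameter values are
unchanged — a pure redistribution across subpopulations, which the
chi-square detects decisively.

## Command line

```
gliamorph segment  --in stack.tif --config cfg.yaml --out run/
gliamorph morph    --labels run/labels.tif --audit run/audit.csv --config cfg.yaml --out run/
gliamorph cluster  --features run/morphometrics.csv --k 3 --seed 17 --out run/
gliamorph report   --run run/
gliamorph simulate stack --archetype ramified --seed 1 --out phantom.tif --truth truth.json
gliamorph simulate table --group-shift 0.25 --seed 9 --out features.csv --truth labels.csv
```

All parameters (voxel spacing, connectivity, noise filter, size gate,
prune length, Sholl step, k, seeds, …) live in one YAML/JSON config; see
`gliamorph.config.PipelineConfig` for the full list and defaults.

## Layout

```
src/gliamorph/
  image_io.py      TIFF z-stack I/O, VoxelGrid container
  config.py        PipelineConfig + YAML/JSON loading
  segmentation.py  Otsu, noise filter, size gate, completeness filter
  morphometry.py   skeletons, eight parameters, soma, Sholl
  clustering.py    zscore → PCA → UMAP → K-means + statistics
  report.py        two-group statistics, run reports
  synthetic.py     phantom stacks and feature tables with ground truth
  cli.py           typer CLI over the above
docs/methods.md    model, conventions, parameter rationale, limitations
```
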