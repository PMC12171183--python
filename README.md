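# imfspat — spatial quantification of intramuscular fat from FF-MRI

Intramuscular fat (IMF) is usually reported as a single mean fat fraction
(FF) per muscle, which says nothing about *where* the fat sits — densely
clumped deposits and sparsely scattered ones can have the same mean yet very
different mechanical and metabolic consequences. `imfspat` is a pipeline for
researchers working with quantitative Dixon-type MRI (e.g. of the ankle
plantar flexors — medial/lateral gastrocnemius and soleus) who want objective
2D and 3D descriptors of IMF spatial distribution, for instance to compare
young and older cohorts or to track fatty infiltration over time.

## Method

1. **Extraction** (per axial slice). The muscle segmentation is eroded by
   2 px to exclude boundary vessels, giving the ROI. With FF(x, y) =
   fat / (fat + water) and FF_median the ROI median, a region is grown from
   the seed argmin |FF − FF_median|, admitting any ROI pixel within radius
   r = 20 px of the region that satisfies ΔFF = |FF − FF_median| ≤ FF_median
   (equivalently FF ≤ 2·FF_median). The grown region is predominantly-muscle
   tissue; its complement within the ROI is the IMF mask. The radius lets
   growth jump across fat bands so enclosed muscle pockets stay muscle.
   Stacking slices, 3D connected components smaller than 4 voxels are
   removed as artifacts.
2. **Along-muscle profiles.** Per slice: mean FF over the ROI and the FF
   pixel percentage (100 · |IMF| / |ROI|), mapped onto percent muscle length
   (0 % distal → 100 % proximal), with Scott's-rule (h = σ̂·n^(−1/5))
   Gaussian-KDE contours, ridge peaks, and the Pearson correlation between
   the two curves.
3. **3D spatial statistics.** IMF voxel centers become a point cloud.
   Delaunay tessellation summarizes unique edge lengths (mm) and tetrahedron
   volumes (mm³), raw and normalized to muscle volume. Ripley's
   K(r) = (V/n²)·Σ_{i≠j} 1[d_ij ≤ r] is compared with the CSR expectation
   (4/3)πr³ and a 95 % Monte-Carlo envelope; L(r) = √(K/π), centered on its
   CSR value, plots CSR as a flat zero line. The maximum clustering distance
   is the largest r at which the envelope's upper bound stays above CSR.
4. **Group inference.** Shapiro-Wilk + Levene checks select two-way
   age × sex ANOVA (Type-II) with Tukey HSD, or Kruskal-Wallis with
   Dunn-Bonferroni post-hocs; Hedges' g quantifies effect sizes.

A synthetic phantom generator (elliptic-cylinder muscle, branch-like
random-walk fat tubes, diffuse clusters, noise singletons, with `young` /
`old` / `sol_diffuse` presets) provides ground truth for every stage.

## Worked example

```python
import numpy as np
from dataclasses import replace
from imfspat import *
from imfspat.phantom import preset, generate_phantom

ph = generate_phantom(replace(preset("old"), seed=7))
res = extract_imf(ph.ff, ph.muscle)
print(f"IMF voxels: {res.n_imf_voxels} (removed {res.removed_small_clusters} small clusters)")

profs = slice_metrics(ph.ff, res)
r = profile_correlation([p.mean_ff for p in profs],
                        [p.ff_pixel_percentage for p in profs])
dens = profile_density(profs, "ff_pixel_percentage")
print(f"Pearson r (mean FF vs FF pixel %): {r:.2f}")
print(f"FF pixel % peak: {dens.peak_value:.1f}% at "
      f"{dens.peak_location_percent:.0f}% muscle length")

cloud = mask_to_point_cloud(res.imf_mask, ph.muscle)
t = delaunay_summary(cloud)
print(f"Delaunay: {t.n_points} points, mean edge {t.mean_edge_length:.2f} mm, "
      f"mean volume {t.mean_tet_volume:.2f} mm^3")
rip = ripley_analysis(cloud, np.arange(1.0, 25.0, 1.0), n_sims=99, seed=0)
print(f"max clustering distance: {rip.max_clustering_distance:.1f} a.u.")
```

prints

```
IMF voxels: 764 (removed 8 small clusters)
Pearson r (mean FF vs FF pixel %): 0.99
FF pixel % peak: 6.5% at 40% muscle length
Delaunay: 764 points, mean edge 4.84 mm, mean volume 5.13 mm^3
max clustering distance: 17.5 a.u.
```

The extractor recovered the planted fat structures and discarded all eight
noise singletons; the mean FF and FF pixel percentage track each other
closely along the muscle (r = 0.99); and the cloud is significantly
clustered (its K curve exceeds the CSR line out to 17.5 voxel units).

The same stages are available from the shell via the `imfspat` console
script (`imfspat extract | profile | spatial | stats | phantom | run`); see
`imfspat --help`.

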