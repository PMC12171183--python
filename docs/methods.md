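# Methods

## Extraction model and its assumptions

The extraction stage assumes the muscle of a healthy, physically active
subject is *predominantly* muscle tissue, so the per-slice ROI median fat
fraction FF_median is a robust estimate of the local muscle-signal baseline.
The growth condition ΔFF = |FF − FF_median| ≤ FF_median then accepts exactly
the pixels with FF ≤ 2·FF_median — low-FF muscle — and rejects high-FF fat.
This reading is the only one under which a median-relative threshold
separates muscle from fat, and it is the one implemented. The slice-adaptive
median tracks anatomical variation along the muscle but would need
rethinking for clinical populations where fat may dominate entire slices
(the median would then no longer estimate the muscle baseline).

Growth is strictly 2D (per slice); 3D connectivity enters only at the
small-cluster filter. The seed is the pixel minimizing ΔFF, with
lexicographic (row, column) tie-breaking for determinism; the grown region
is the fixed point of repeatedly admitting any qualifying pixel within
Euclidean distance r of the region, so the result is independent of which
qualifying pixel seeds it (tested). A `single_pass` flag preserves the
non-transitive one-sweep alternative. The radius is deliberately generous
(default 20 px) so growth can jump across fat bands up to ~r pixels wide and
keep enclosed muscle pockets out of the IMF mask; because low-FF tissue is
spatially contiguous in practice, the reachable set saturates and results
are insensitive to r over 5–30 px (measured: identical masks on phantoms).

### Parameters

| parameter | default | units | why |
|---|---|---|---|
| erosion_pixels | 2 | px | excludes boundary blood vessels from the ROI |
| search_radius_r | 20 | px | wide enough to jump fat bands; results r-insensitive 5–30 |
| min_cluster_voxels | 4 | voxels | smallest spatially coherent deposit; below it, likely artifact |
| connectivity_3d | 26 | – | "connected voxels" taken most permissively; exposed as a parameter |
| median_scale | 1.0 | – | multiplies FF_median for threshold-sensitivity analysis |

Erosion uses a 4-connected cross element applied n times. Slices emptied by
erosion are skipped and recorded, not zero-filled. The 3D filter counts
components at 26-connectivity by default; 6 and 18 are available and the
choice is covered by the sensitivity tests.

## Profiles

Mean FF is averaged over the *full* eroded ROI (not only IMF pixels), so it
measures overall fat magnitude; the FF pixel percentage measures spatial
extent. Percent muscle length maps the first analyzed slice to 0 % (distal)
and the last to 100 % (proximal); the orientation flag is a required input
because NIfTI orientation codes are unreliable across exporters.

Density contours use a product-Gaussian KDE with per-axis Scott's-rule
bandwidths h = σ̂·n^(−1/5) (σ̂ the sample standard deviation; the constant
is the d=1 case of σ̂·n^(−1/(d+4))). Bandwidths are computed per participant
curve and averaged, so pooling identical participants leaves the density
unchanged. The grid is 100×100 over the observed range extended by 4
bandwidths per axis (density integrates to 1 within 1e-3). Peaks are read
off the density ridge — the most probable metric value per length column —
restricted to the observed length range. Note that KDE smoothing along the
length axis (bandwidth ≈ 14 % length for a typical 30–40-slice muscle) can
shift the ridge peak of a skewed curve by up to about one bandwidth relative
to the raw-curve argmax; for gradient-detection purposes (proximal vs distal
half) this is immaterial.

## Spatial statistics

Points sit at voxel centers, (index + 0.5)·spacing, in mm; the convention is
symmetric under mask reflection. Anisotropic spacing (e.g. 1.1×1.1 mm
in-plane, 2 mm slices) is carried into all mm-valued geometry.

Delaunay summaries count each edge once regardless of how many tetrahedra
share it (per-tetrahedron counting would overweight interior edges).
Normalization divides edges by muscle_volume^(1/3) and volumes by
muscle_volume, the dimensionally consistent choices; raw mm/mm³ values are
always reported alongside. Degenerate (coplanar) clouds are retried once
with a fixed-seed uniform jitter ≤ 1e-6 mm.

Ripley's K uses the 3D closed-form CSR expectation (4/3)πr³ and, by default,
the muscle bounding box as reference domain (the mask-restricted domain,
with uniform-within-mask CSR sampling, is available). No edge correction is
applied; uncorrected K is biased low near boundaries, but the Monte-Carlo
envelope is simulated in the same domain with the same estimator, so the
data-vs-envelope comparison is internally consistent (the calibration test
confirms ~95 % coverage). Ripley radii default to voxel units ("a.u.");
Delaunay metrics are always mm. L(r) is the Besag square-root transform
√(K/π), centered by subtracting the same transform of the CSR expectation so
CSR plots at zero; the literal quadratic reading K/π and the standard 3D
transform (3K/4π)^(1/3) − r are available as options. The maximum clustering
distance interpolates linearly between radius grid points for the last
crossing of the envelope's upper bound over the CSR line; for a single
subject the rule is applied to the subject's own K curve against the CSR
line, for groups to the across-participant envelope.

## Group inference

Branch selection is a pure threshold rule: parametric iff every group's
Shapiro-Wilk p > 0.05 and Levene p > 0.05 (Levene median-centered, i.e.
Brown-Forsythe — the robust common default). The ANOVA uses Type-II sums of
squares, appropriate for unbalanced cells when no interaction is expected;
on balanced data it reproduces the classical decomposition exactly (tested
against a from-scratch sums-of-squares oracle). Dunn's post-hoc test is
implemented directly (rank-sum z statistics with tie correction, Bonferroni
factor = number of pairwise comparisons); Tukey HSD comes from statsmodels.
The Friedman test is provided as a repeated-measures check of a metric
across the three muscles within participants and is reported before
Kruskal-Wallis in the nonparametric branch. Groups with n < 3 force the
nonparametric branch. α = 0.05 throughout.

## Phantom generator

The phantom emulates the study conditions the pipeline targets: a low-FF
muscle background (truncated normal 0.03 ± 0.01, clipped to [0, 0.05] so
background always satisfies FF ≤ 2·FF_median by construction), branch-like
tubular clusters (persistent in-plane random walks along the long axis,
FF ~ U(0.25, 0.60)), optional diffuse spherical clusters (the soleus-like
multi-focal mode), and isolated high-FF noise singletons placed ≥ 2 voxels
from every true cluster so filter behavior is unambiguous. The default grid
is 44×44×28 voxels at 1.1×1.1×2.0 mm, echoing typical Dixon in-plane/slice
geometry at a size that keeps a full multi-phantom analysis interactive on
one CPU. Presets: `young` (4 branches), `old` (12 branches — 3×, giving the
denser clustering of older muscle), `sol_diffuse` (2 branches + 6 blobs).
Branch starts are biased toward the proximal end via `proximal_gradient`
(weight 1 + g·z/z_max), reproducing the distal→proximal accumulation
pattern. All structures are planted one pixel inside the post-erosion ROI so
the ground truth equals what a correct extraction should retain; truth
fragments below 4 voxels are pruned from the truth for the same reason.

The phantom deliberately omits several features of real data: MR noise and
bias fields, partial-volume mixing at fat/muscle interfaces, water-fat
swaps, anatomical muscle taper, and the IMCL/EMCL distinction. Passing tests
therefore demonstrate the correctness and internal consistency of the
algorithms under separable conditions — not robustness to acquisition
artifacts, which would require real or physics-simulated data.

## Problem sizes and numerical choices

The test suite and the reproduction script use 44×44×28 phantoms, cohorts of
10 + 10, CSR envelopes of 199 simulations, and oracle clouds of n ≤ 50 —
sizes chosen so a full run completes in minutes while leaving every
statistical check well-powered (the simulated age effect has Hedges' g > 1).
CSR-envelope calibration reuses one envelope across test clouds: the
envelope is a deterministic function of (n, domain, radii, seed), so this is
exact. Floating-point agreement between implementation and brute-force
geometry oracles is asserted at 1e-9 (measured ~1e-15). FF is stored in
[0, 1] internally; all human-facing reports print percent.

## Known limitations

- The median-relative threshold presumes muscle-dominated slices; clinical
  high-FF data would need a different baseline estimate.
- No Ripley edge correction (an optional translation correction would be the
  natural extension); absolute K values are domain-dependent, comparisons
  against same-domain envelopes are not.
- Whether the original 2D-notation growth and "connected voxels" filter were
  intended per-slice/3D respectively is not fully determined by their
  descriptions; the per-slice growth + 3D filter combination implemented
  here is the one consistent with all stated behavior, and both the
  connectivity and the single-pass alternative are exposed as options.
- The phantom's branch model is a geometric stand-in (persistent random
  walk), not a vascular atlas; it reproduces the morphology class, not
  anatomy.
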