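# Methods

This note documents the models, discretizations, parameter choices and known
limitations of the `nucmorph` pipeline, in the order the stages run.

## Masks and connectivity

Volumes are `(z, y, x)` integer grids with per-axis physical spacing
(default 1 voxel unit when no calibration is available); all physical
coordinates are `index × spacing`, and anisotropic spacing is supported
throughout. Foreground objects use 26-connectivity with 6-connected
background — the standard well-composed pairing — and components below a
minimum size (default 50 voxels, configurable) are discarded as
segmentation specks. Nucleoli are assigned to the nucleus whose mask
contains their centroid voxel; centroid containment is robust to
boundary-touching voxels, which an any-overlap rule is not. Nuclei without
internal nucleoli are excluded so that every feature vector has a complete
nucleolar block. When two nucleolar stains are available, each nucleolar
mask volume is processed independently; the pipeline does not merge
channels before counting.

## Surface reconstruction

Each object is modeled as a genus-zero closed surface. The loop is:

1. **Meshing.** The mask is cavity-filled, repaired to be well-composed
   (below), zero-padded by one voxel and iso-surfaced at the 0.5 level by
   marching cubes; only the largest boundary component is kept. The result
   is validated: watertight, consistent winding, Euler characteristic 2,
   positive signed volume.
2. **Eigen-projection.** The Laplace–Beltrami operator is discretized with
   the cotangent-weight stiffness matrix `L` and a lumped barycentric mass
   vector `m`; the generalized symmetric problem `Lφ = λMφ` is solved for
   the `k` smallest eigenpairs by shift-invert Lanczos (ARPACK) with a
   fixed start vector, falling back to a dense solver for small meshes or
   near-complete bases. Vertex coordinates are replaced by their projection
   onto the span of the first `k` eigenfunctions. Default `k = 100`, which
   on a nucleus-scale object retains roughly the spherical-harmonic content
   up to degree ~9 — low-frequency shape, no voxel staircase.
3. **Distortion.** Per-vertex displacement between mesh and projection,
   divided by the mesh's mean edge length (scale-free).
4. **Deformation.** Boundary voxels whose vertices exceed the distortion
   threshold are flipped to background in order of decreasing distortion.
   A flip must be a *simple point* under the 26/6 pairing (Bertrand's two
   topological numbers equal 1: neither foreground nor background
   connectivity changes) **and** must not introduce a new critical
   configuration (a 2×2 axis-plane square with only a diagonal foreground
   pair, or a 2×2×2 cube with an antipodal pair) — the voxel patterns whose
   iso-surface pinches into tunnels. Both conditions together keep the
   deformed mask's surface a manifold of the same genus. If a deformation
   nevertheless yields an unmeshable mask, it is reverted and iteration
   stops at the previous (valid) state.

Steps 1–4 iterate until no voxel flips or 10 iterations; the final surface
is the eigen-projection of the final mask boundary, and its enclosed volume
is checked against the mask voxel volume (default tolerance 5%; a violation
is logged as a warning rather than raised, because sub-300-voxel nucleoli
legitimately carry a few percent of discretization error).

**Distortion threshold.** When not set explicitly, the threshold is fixed
on the first iteration at `max(3 × median displacement, 0.75)` mean edge
lengths. The 3×median term is a robust outlier scale; the 0.75 floor
matters because boundary meshes of binary masks carry an irreducible
staircase ripple whose distortion stays below ~0.5 mean edge lengths at any
resolution — without the floor, smooth objects at coarse resolution would
have their real boundary eroded. Genuine spurious features (a 1-voxel-wide
spike several voxels long) exceed the floor clearly. The threshold is
frozen after the first iteration so the above-threshold vertex count
decreases monotonically as features are removed.

**Well-composedness repair.** Binary masks can contain critical
configurations out of the box (e.g. two objects merged through a voxel
diagonal); these are repaired before meshing by promoting a background
voxel of each offending pattern to foreground (ties at the iso-level broken
toward foreground). The repair touches isolated voxels only and adds, not
removes, volume, so it cannot erode anatomy.

## Morphometry

Principal curvatures use the discrete mean-curvature normal (cotangent
formula, signed by the outward vertex normal) for H and the angle deficit
for the Gaussian curvature K, then `κ = H ± sqrt(max(H² − K, 0))`; negative
discriminants — numerically inconsistent estimates — are clamped to an
umbilic. Both H and K fields are regularized by two passes of mass-weighted
one-ring averaging before extracting κ: the raw pointwise estimators are
unbiased but noisy on irregular iso-surface triangulations, and because the
shape index has κ₂ − κ₁ in its denominator the noise biases SI away from
±1 at umbilic points (a smooth sphere mesh reads ~0.90 without smoothing,
~0.99 with two passes) while the area-weighted means of MC and CV move by
well under 1%. Sign convention: outward normals, convex surfaces positive,
so a sphere of radius r has κ₁ = κ₂ = 1/r.

Surface means of MC/SI/CV are weighted by barycentric vertex areas (one
third of incident triangle area), making them mesh-resolution independent;
uniform vertex means would drift with triangulation density. The umbilic
branch of SI uses a relative tolerance of 1e-8 on κ₂ − κ₁.

Volume is the signed-tetrahedra sum (discrete divergence theorem), exact
for closed meshes and translation-invariant; area is the triangle-area sum.

Fractal dimension is estimated by box counting: the surface is sampled on a
deterministic barycentric grid dense enough that no box crossed by a
triangle is missed (≥10 samples per smallest box per triangle), boxes of
size ε are counted on the dyadic ladder {1/4, 1/8, 1/16, 1/32} of the
largest bounding-box extent, and FD is the least-squares slope of log N(ε)
against log 1/ε (the fit R² is returned alongside). Points on the upper
bounding faces are clipped into the last box layer — without this the flat
surface reads ~1.76 instead of 2. Box counting with axis-aligned boxes is
exactly invariant under 90° rotations but only approximately (±~0.1) under
arbitrary rotations, and smooth closed surfaces read slightly above 2
(~2.1) on this scale ladder; both are inherent to the estimator, which is
used as a roughness index, not an absolute dimension.

## Features and classification

Each nucleus contributes 31 features: its 6 measures, the nucleolus count
(raw integer, uncapped), and Avg/Min/Max/Var of each measure over its
nucleoli. "Higher moments" are concretized as the unbiased sample variance
(ddof = 1, zero for a single nucleolus); skewness/kurtosis are not
included. Values are aggregated after sorting so the statistics are exactly
permutation-invariant, and the mean is clipped into [min, max] so the
ordering invariant survives float round-off. No feature normalization is
applied — the tree ensembles used downstream are scale-invariant.

L2OGO enumerates every opposite-class image pair as a test fold (n_A × n_B
folds); training uses all remaining images with the majority class
uniformly sub-sampled to the minority count. Model presets expose the two
benchmark hyperparameter sets — stochastic gradient boosting (1,500
learners, depth 8, subsample 0.5) and random forest (1,000 trees, depth 12,
40% features per split) — plus a light `fast-rf` preset (100 trees) for
routine runs. Cell-set classification draws, per bootstrap repetition and
per test image, one set of cells uniformly from that image (without
replacement when the image has enough cells, with replacement otherwise),
so each set has a single true label; the set label is the majority vote of
member hard labels (probability threshold 0.5) with ties broken by the mean
member probability, and the set score for AUC is that mean probability
(vote fractions would be an equally defensible choice; averaged
probabilities are used and documented). Metrics are averaged over 1,000
repetitions per fold and summarized as mean ± SD across folds; no
multiple-testing correction is applied. Default set sizes are the odd
integers 3–31. Feature importances are impurity-based, averaged across
folds, normalized to sum to one.

## Synthetic data

The phantom generator voxelizes implicit solids at voxel centers with no
anti-aliasing, matching binary-mask semantics. Analytic references: sphere
V = 4πr³/3, SA = 4πr²; ellipsoid V = 4πabc/3 and SA by Gauss-grid
quadrature (relative error < 1e-5); cube V = s³, SA = 6s²; regular
octahedron parameterized by circumradius c (L1 ball |x|+|y|+|z| ≤ c) with
V = 4c³/3, SA = 4√3c²; three overlapping spheres with linearly aligned
centers by inclusion–exclusion of the pairwise lens volumes (spacing d
constrained to r ≤ d < 2r so adjacent spheres overlap and the outer pair
does not).

The population generator emulates the structure of real mask datasets:
several images per condition, several nuclei per image, 1–4 nucleolar
spheres strictly inside each nucleus. Class templates default to spheres
(r = 20) versus equal-volume 1.3:1 prolate ellipsoids, with 5% per-axis
uniform scale jitter; all randomness flows from one seeded generator, so
populations are reproducible. What the phantoms do *not* emulate: real
segmentation noise, concave or folded nuclei, intensity texture, anisotropic
acquisition, or touching objects — so passing tests demonstrate geometric
correctness and pipeline mechanics, not robustness to real microscopy
artifacts.

For the qualitative curvature-ordering comparison (sphere vs ellipsoid vs
overlapping spheres) the suite uses an equal-volume sphere/2:1-prolate pair
so object size does not confound shape — for near-spherical triaxial
ellipsoids the surface-averaged MC is numerically indistinguishable from
the equal-volume sphere's 1/r, whereas a 2:1 prolate gives a clear gap —
and overlapping spheres with r = 11, d = 18, small enough that the
high-curvature lobes dominate the negative-curvature neck creases.

## Problem sizes

Validation phantoms run on 128³ grids (nucleus-scale shapes, r ≈ 20
voxels); the topology suite uses 50 randomized phantoms on ~40³ grids; the
classification suite uses a population of 3 images per class × 4 nuclei
(r = 10 spheres vs equal-volume prolates) with 1,000-repetition bootstraps.
These sizes were chosen so the complete validation runs in minutes on a
single CPU while keeping every object large enough (≥ several hundred
voxels) for stable curvature estimation.

## Known limitations

* The eigen-projection smooths sharp creases and corners: faceted solids
  lose a few percent of surface area at their edges (the cube reads ~5.7%
  low), which is the expected cost of resolving singular points smoothly.
* The distortion threshold floor assumes roughly isotropic voxels; strongly
  anisotropic spacing changes the staircase ripple amplitude and may
  warrant an explicit threshold.
* Box-counting FD is a relative roughness index at the chosen scale ladder,
  not an absolute Hausdorff dimension.
* Objects below ~8 voxels cannot be meshed and are rejected; objects below
  a few hundred voxels carry percent-level discretization error in all six
  measures.
* The classification stage assumes a binary condition design; multi-class
  problems would need a different fold construction.
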