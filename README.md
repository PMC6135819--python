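# nucmorph

3D morphometry of cell nuclei and nucleoli from binary segmentation masks.

Changes in nuclear and nucleolar shape accompany many cellular processes —
cell-cycle synchronization, epithelial–mesenchymal transition, malignant
transformation — and 3D fluorescence microscopy routinely produces binary
masks of these compartments. `nucmorph` turns such masks into quantitative
shape descriptors and evaluates how well those descriptors discriminate
between experimental conditions. It is aimed at quantitative microscopists
and image-analysis developers who have per-object 3D masks (multi-page TIFF)
and want reproducible, geometry-grounded features rather than 2D proxies
like diameter or bounding-box size.

## What it computes

**Surface reconstruction.** Each mask's boundary is modeled as a closed
genus-zero 2-manifold, triangulated by iso-surfacing and then smoothed by
*Laplace–Beltrami eigen-projection*: the vertex coordinate functions are
projected onto the span of the first *k* eigenfunctions of the surface's LB
operator (cotangent discretization). Eigenvalue magnitude plays the role of
frequency, so the truncation is a spectral low-pass filter that removes
voxelization staircase and spurious segmentation features while preserving
anatomy. Vertices the low-pass basis cannot represent move far under
projection; this *metric distortion* localizes spurious features, which are
then removed from the mask by a topology-preserving (simple-point,
well-composed) deformation. Meshing, projection and deformation iterate to
convergence.

**Morphometry.** From the reconstructed surface with principal curvatures
κ₁ ≤ κ₂ (eigenvalues of the second fundamental form), six measures form the
object signature:

| measure | definition |
|---|---|
| volume *V* | ∭ I_D dx dy dz (signed-tetrahedra sum over the closed mesh) |
| surface area *SA* | ∬ \|r_u × r_v\| du dv (triangle-area sum) |
| mean curvature *MC* | (κ₁ + κ₂)/2 |
| shape index *SI* | (2/π)·arctan((κ₁+κ₂)/(κ₂−κ₁)) ∈ [−1, 1] |
| curvedness *CV* | √((κ₁² + κ₂²)/2) |
| fractal dimension *FD* | box-counting slope of log N(ε) vs log 1/ε |

Curvature descriptors are reported as area-weighted surface means.

**Feature assembly.** Nucleoli are assigned to the nucleus containing their
centroid; nuclei without internal nucleoli are excluded. Each nucleus yields
a fixed-length 31-feature vector: its own 6 measures, the nucleolus count,
and Avg/Min/Max/Var statistics of each measure over its nucleoli.

**Classification.** Condition discrimination is evaluated with
Leave-2-Opposite-Groups-Out (L2OGO) cross-validation — every fold holds out
one whole image per class, so batch effects cannot leak between train and
test — using gradient-boosting or random-forest presets, class balancing by
random sub-sampling, and bootstrapped cell-set classification (majority vote
over sets of 3–31 cells, 1,000 repetitions) with accuracy, precision,
sensitivity, AUC, and impurity-based feature importance.

A `synthetic_shapes`-style phantom generator (spheres, ellipsoids, cubes,
octahedra, 3 overlapping spheres, and labeled two-class populations with
nucleoli) provides analytic ground truth for validation, so the entire
pipeline is testable without any external dataset.

## Worked example

Measure a voxelized sphere of radius 20 on a 64³ grid:

```python
from nucmorph import (PhantomSpec, make_phantom, split_objects,
                      reconstruct_surface, compute_signature)

vol, spec = make_phantom(PhantomSpec("sphere", (20.0,), grid_shape=(64, 64, 64)))
(obj,) = split_objects(vol, min_voxels=8)
mesh = reconstruct_surface(obj)
sig = compute_signature(mesh)
```

which prints, when the six fields are compared with their analytic values:

```
volume              33516.0   (analytic 33510.3)
surface area         5028.8   (analytic 5026.5)
mean curvature       0.0498   (analytic 1/r = 0.0500)
shape index          0.9911   (sphere: 1)
curvedness           0.0498   (analytic 1/r = 0.0500)
fractal dim.         2.1170   (smooth surface: 2)
```

Volume and area agree with the closed forms to well under 1% — the raw
iso-surface of a binary mask overestimates the area by ~9%, and the spectral
smoothing recovers it — while MC and CV recover 1/r, SI is ~1 as expected
for an umbilic surface, and FD sits near 2 for a smooth shape.

The same works from the shell on any multi-page TIFF mask:

```bash
nucmorph measure my_mask.tif --out signatures.csv
nucmorph generate --out-dir demo --images-per-class 3 --seed 1   # synthetic data
nucmorph run --manifest demo/manifest.csv --out-dir demo-out --model fast-rf
nucmorph validate-synthetic                                      # phantom error table
```

`nucmorph run` writes `features.csv` (one row per nucleus, 31 features),
per-set-size metrics CSVs, a ranked feature-importance table, and a
`run_manifest.json` recording the effective configuration — reruns with the
same config are byte-identical.

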