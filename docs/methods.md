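# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `mandssm`, in the order data flows through the pipeline.

## Synthetic cohort generator

The generator stands in for a cadaveric CT cohort and defines the study
conditions under which everything else is validated.

**Base surface.** A closed, genus-0 horseshoe: a parametric arch
(body + symphysis, elliptical cross-section ~9 × 4.6 mm half-axes, arch
half-width ~30 mm, anteroposterior depth ~35 mm) whose posterior ends rise
~28 mm into ramus-like plates carrying a condyle-like end cap and a
coronoid-like radial bump (compact cos² windows, so their support is
strictly local). The right half is constructed and mirrored vertex-for-
vertex about x = 0, making the mesh bilaterally symmetric to machine
precision; the requested vertex count is met exactly by splitting midline
ring edges (midpoints stay on x = 0). The seed jitters the global
proportions by ±3%. Seven landmark vertex ids (condyles, coronoids, gonial
angles, mental protuberance) are recorded at construction.

**Planted modes.** Five analytic displacement fields — non-uniform growth
(z gain > y gain > x gain, i.e. height > length > width), length/width
ratio, gonial spread, ramus bending, chin skew — are first projected
orthogonal to the six rigid-motion fields (translations and infinitesimal
rotations about the centroid), then Gram–Schmidt orthogonalized and scaled
to unit per-coordinate RMS. Without the rigid projection the 6-DOF
Procrustes alignment of the pipeline strips rigid components from the
planted fields and tilts the recovered subspace (measured: 17° third
principal angle, vs. < 0.7° with the projection).

**Defaults (the study conditions).** n = 200 samples, 900 base points,
K = 3 modes with amplitudes (6.0, 2.5, 1.8) mm per SD, vertex noise
0.3 mm (5% of the leading amplitude). These amplitudes were chosen once so
that the planted spectrum mirrors the variance structure reported for the
cadaveric cohort this generator emulates (mode 1 ≈ 79% of total variance).
Ages are drawn from a right-skewed discrete distribution over 1–12 years
(category weights 12, 75, 215, 187, 107, 116, 47, 29, 22, 28, 15, 8,
matching the skew toward ages 2–6 of such collections). The mode-1 weight
is `standardize(slope·z_age + 0.35·ε)`; at the default slope 1.0 the
planted Spearman correlation with age is ≈ 0.91–0.93. `mode1_age_slope` is
the dimensionless age-coupling strength; the millimetre amplitude of the
growth mode is carried by `mode_sds[0]` like every other mode, so the
realized mm-per-age-SD is `sd₁·slope/√(slope²+0.35²)`.

**What the generator does *not* emulate:** dentition and alveolar
structure (the "dental region" is just the superior band of the anterior
body), CT noise, beam hardening, segmentation artifacts, left/right
asymmetry of real anatomy (the default cohort is exactly symmetric), and
age-dependent variance structure. Passing recovery tests therefore show
that the *pipeline machinery* is correct under known truth — not that real
mandibles satisfy a 3-mode linear model.

**Voxelization.** Scan-line parity: triangles are rasterized in the xy
plane, z-crossings per grid column are sorted, and voxel centers between
even/odd crossing pairs are labelled interior (intensity 1000, background
0). A 1e-7 mm vertex jitter avoids degenerate center-on-edge cases. On a
10 mm sphere at 0.5 mm spacing the interior count matches the analytic
volume within 0.2%.

**Observer perturbation.** A Gaussian-kernel random field (width 5 mm,
64 control points) confined to the selected region, tapered linearly to
zero within one kernel width of the region boundary, scaled to a requested
RMS magnitude. Vertices outside the region are untouched exactly.

## Volume reconstruction

Interpolation refines the declared slice axis only (linear, physical
extent preserved; 1.0 mm → 0.5 mm maps N slices to 2N−1). Thresholding
defaults to the Otsu split when no value is configured. Morphological
closing uses a ball structuring element with per-axis voxel radii rounded
up from the physical radius (anisotropic grids); the input is padded so
closing is extensive, and a sub-voxel radius warns and degenerates to the
identity. The closed mask is Gaussian-smoothed (σ in mm, converted
per-axis) and isosurfaced with marching cubes at occupancy 0.5 — unbiased
under symmetric smoothing — keeping the largest connected component.
Defaults: 0.5 mm target slices, 1.0 mm closing radius, 0.6 mm smoothing σ.
Round trip (rasterize at 0.4/0.4/1.0 mm → reconstruct) lands 0.12–0.15 mm
from the source surface, about one tenth of the voxel diagonal.

## Mesh preprocessing

**Uniform remeshing** is classic isotropic edge-equalization: split edges
longer than 4/3 L, collapse edges shorter than 0.8 L (link-condition
guarded, batch-conflict-free), flip edges toward valence 6, tangentially
relax and re-project onto the input surface; the target edge length L is
recalibrated up to three times so the vertex count lands within ±10% of
the target. Measured edge-length CV after remeshing: 0.10 (sphere), 0.15
(mandible at 5801 points), with surface deviation well below 0.5% of the
bounding-box diagonal.

**Leveling** removes the selected patch and fills each hole with a
harmonic (uniform-weight Laplace) patch: the boundary loop is mapped to a
circle by arc length — boundary edges are then convex-hull edges of the 2-D
Delaunay triangulation, which guarantees a watertight stitch — interior
points are laid on a polar grid at the local edge length, and interior 3-D
positions solve the Dirichlet problem with the loop fixed. A planar
boundary yields a planar fill (harmonicity); non-selected vertices are
preserved bit-identically.

**Mirroring** estimates the midsagittal plane (principal-axis candidates
refined by Nelder–Mead on the reflection misfit of a surface sample
against a dense sample k-d tree; the reported misfit is the exact
point-to-surface value), cuts the mesh at the plane, snaps cut vertices
onto it, and stitches the kept half to its exact reflection. The output is
symmetric by construction (residual ~1e-14); which half is kept is a flag
(default left). On generator output the estimated plane recovers x = 0
within 0.2° and 0.05 mm.

## Correspondence

**Affine ICP (9 DOF).** The transform is `R·diag(s)·B·(y−c) + t` with `B`
the source's principal axes (the scaling axes; an explicitly documented
choice). Correspondence uses exact projections onto the faces of the k
nearest surface samples (k-d tree over ~4P samples). Per-axis scale is
confined to [0.80, 1.25] × a correspondence-free estimate (matched
standard-deviation ratios along the paired axes): one-way nearest-point
ICP otherwise collapses scale on thin structures (and closest-point-both-
ways, tried first, exerts a coverage force that *stretched* the identity
case by 15%). Updates are closed-form coordinate descent (Kabsch rotation,
per-axis least-squares scale, centroid translation), so the RMS trace is
non-increasing. Principal-axes pose candidates (4 sign combinations) are
opt-in (`pose_search`): for bilaterally symmetric cohorts the left/right-
flipped basin is indistinguishable by surface distance and must not be
entered silently.

**CPD.** Standard non-rigid coherent point drift: the template points are
Gaussian-mixture centroids displaced by `v = G W` (G the Gaussian Gram
matrix of width β over the template), each EM iteration solves
`(diag(P1) G + λσ² I) W = P X − diag(P1) Y` and re-estimates σ², with a
uniform outlier component (w = 0.1 default). Inputs are centered per set
and scaled by the target RMS. The penalized negative log-likelihood is
logged and is non-increasing (ECM). Numerical policies that matter:

- **σ² chaining:** later stages of a schedule start from the previous
  stage's σ² instead of the classic whole-shape initialization
  (re-melting alignment each stage cost ~6 mm of correspondence error);
  the first stage after ICP starts from the nearest-neighbor residual.
- **σ² plateau stop:** once σ² changes by < 0.1% per iteration the fit no
  longer improves and further EM only lets correspondence creep
  (Lloyd-style centroid rebalancing); iteration stops there (drift capped,
  ~5× faster).
- **σ² collapse** below machine tolerance clamps and terminates with a
  warning.
- Optional **area-weighted mixture components** (`point_weights='area'`)
  remove the density-equalization force when the template sampling is
  non-uniform (measured 8.4 mm → 2.0 mm identity drift for a swept-grid
  template); the default pipeline instead uses a uniformly remeshed
  template with classic uniform weights.

**Staged mapping.** Defaults (β, λ) = (2.0, 3.0) → (1.5, 2.0) →
(1.0, 1.0) on unit-normalized coordinates, w = 0.1, tol 1e-5, ≤150
iterations per stage — the published recommended ranges; all configurable,
and a schedule must have non-increasing (β, λ). After the stages, one
smoothness-regularized snap (local kernel, 2× template point spacing;
λ = 0.1 × the last stage's) pulls the points onto the *exact* surface:
this removes the sampled-GMM discretization floor (template-onto-own-mesh
quality 0.34 mm → 0.03 mm) while a rough projection field — the signature
of misregistration — is still damped. Mapping quality is the mean distance
of the mapped points to the target surface; mappings above the 0.5 mm
threshold retry once with halved λ and are otherwise flagged failed and
excluded downstream (never silently dropped).

**Template refinement** maps the template onto a seeded random subset,
6-DOF-aligns the successful mappings (≥80% must succeed), averages
pointwise, and rigidly re-aligns the average back into the template frame;
one pass by default.

## Alignment, PCA, synthesis

GPA iterates optimal rotation+translation to the evolving mean until the
mean moves < 1e-7 mm; no scaling, so centroid sizes are preserved exactly
and growth stays in the data. PCA runs through the n×n dual problem (the
3P×3P covariance is never materialized), eigenvector signs are fixed by
making the largest-magnitude component positive, and weights are SD units
(sample covariance 1/(n−1) makes their SD exactly 1; the covariance
divisor is immaterial for variance fractions). `synthesize` is the linear
reconstruction; `project_new_sample` optionally 6-DOF-aligns to the model
mean first (`align=False` for inputs already in the model frame). The
reported reconstruction error is the mean of per-point Euclidean norms, so
nested-projection monotonicity holds up to a ~0.1% tolerance (the L2 norm
is strictly monotone; the mean of norms is not).

## Evaluation suite

Compactness is the cumulative eigenvalue fraction. Generalization rebuilds
the PCA per left-out sample with the alignment held fixed from the full
cohort (per-fold re-alignment available behind `realign=True`; the choice
is a documented open point). Specificity draws standard-normal weights,
synthesizes, and averages the distance to the nearest training shape
(1000 draws by default, seeded). Horn's parallel analysis simulates
row-variance-matched Gaussian matrices (the coordinates have heterogeneous
variances, so classic unit-variance noise would be mis-scaled) and returns
the *leading run* of real eigenvalues above the 95th percentile of their
rank — the "first k modes exceed" reading; counting isolated later
exceedances would add the rule's expected false positives (measured 0–6 on
pure noise vs 0–1 for the leading run). Surface distance maps cast rays
along both vertex normal directions with a cap of 5× the mean edge length
and fall back to the nearest surface point. Spearman uses average ranks
with the t-approximation p-value; constant input reports NaN. The ICC is
ICC(2,1) — two-way random effects, absolute agreement, single rater — with
the F-based confidence interval (McGraw & Wong); it matches an independent
ANOVA implementation to 1e-5 and degenerates to 0 (flagged by a collapsed
CI) when between-subject variance vanishes. p-values are reported, never
thresholded inside the library.

## Problem sizes

Desk-scale defaults used by the analysis scripts and tests: the main
recovery study uses n = 200 samples at 900 points; the registered pipeline
runs 50 samples with a 480-point template (the method is resolution-
parametric — the same code built the 5801-point template checks);
leave-one-out curves use 40–60 folds; specificity uses 200–1000 draws.
These sizes keep every script in minutes on one CPU.

## Known limitations

- **Tangential correspondence noise.** The tangential position of a point
  on a smooth surface is not identifiable from geometry alone. Measured on
  synthetic cohorts, the per-sample correspondence error of the
  registration chain is ~1.5–2.5 mm (mean), largely independent of planted
  amplitude and template resolution; mapped landmarks track anatomy well
  below the ~8 mm deformation scale but do not reach the sub-millimeter
  regime reported from visual comparison on real mandibles, whose surfaces
  carry far more anchoring detail. Quantities that depend only on surface
  geometry (overlay distance, registration success, variance structure,
  age correlation) are unaffected; per-point attributions should be read
  with this noise floor in mind.
- Generalization holds the Procrustes alignment fixed across folds by
  default; with very small cohorts this slightly flatters the curve.
- The bilateral symmetry of the default cohort makes the left/right flip a
  true symmetry; pose search is therefore off by default and posed inputs
  need either `pose_search=True` or an approximate common orientation.
- The reconstruction chain assumes an air-surrounded object (clean
  bimodal histogram); no HU calibration or metal-artifact handling.
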