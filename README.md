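# mandssm — a statistical shape model of the growing mandible

`mandssm` builds and evaluates point-distribution shape models of
mandible-like surfaces. It re-implements, as a tested and reusable Python
package, the pipeline used to model mandibular shape and growth from large
CT-scanned cohorts: voxel reconstruction, uniform remeshing and
dental-region leveling, dense semi-landmark correspondence, scale-retaining
Procrustes alignment, PCA, and a standard model-quality suite. Because no
cadaveric CT data can ship with the code, a first-class synthetic cohort
generator produces mandible-like surfaces with *known* planted shape modes
and an age covariate, so every stage of the pipeline can be validated by
parameter recovery.

Intended users: researchers in craniofacial morphometrics and
statistical shape modelling who want a transparent, scriptable
reference implementation of this pipeline, and methodologists who need a
controlled test bed with ground truth.

## The model

Each sample surface is represented by the same `P` semi-landmarks (points
placed by geometric correspondence, not anatomical definition), obtained by
deforming one template onto every sample:

1. **9-DOF affine ICP** — rotation, translation and per-axis scaling (along
   the source's principal axes), estimated by iterated closest-point
   correspondence;
2. **Coherent point drift (CPD)** — non-rigid Gaussian-mixture registration
   with a motion-coherence penalty, applied in stages with decreasing
   kernel width `β` and regularization `λ`, so the fit tightens
   progressively.

The `n` mappings are aligned by **generalized Procrustes analysis with six
degrees of freedom** (rotation + translation only — size differences carry
growth and are deliberately retained), stacked into a shape matrix
`X ∈ R^{3P×n}` (a 5801-point template gives 17,403-dimensional shape
vectors), and decomposed by PCA of the sample covariance
`C = (1/(n−1)) Σᵢ (xᵢ−x̄)(xᵢ−x̄)ᵀ` through the n×n dual eigenproblem.
A shape is synthesized from SD-unit mode weights `w` as

```
x(w) = x̄ + Σₖ wₖ √λₖ vₖ
```

so the mean shape scores 0 on every mode and ±3 SD spans the cohort.
Model quality is reported as **compactness** (cumulative variance
fraction), **generalization** (leave-one-out reconstruction error vs.
retained modes), **specificity** (distance of random instances to their
nearest training shape), and the number of **dominant modes** by Horn's
parallel analysis (25 row-variance-matched noise simulations, 95th
percentile, leading run). Mode weights are correlated with dental age by
Spearman's rank test; inter-observer agreement of weights uses the
two-way random-effects, absolute-agreement, single-rater ICC.

The synthetic cohort plants K mutually orthogonal displacement fields on a
parametric, exactly bilaterally symmetric horseshoe surface: mode 1 is
non-uniform "allometric growth" (height gain > length gain > width gain)
whose weight tracks a dental-age covariate drawn from a right-skewed 1–12
year distribution; the remaining modes (length/width ratio, gonial-angle
spread, ramus bending, chin skew) are age-independent; i.i.d. vertex noise
is added on top. The fields are orthogonalized against rigid motions so the
planted subspace is invariant under the 6-DOF alignment.

## Worked example

```python
import numpy as np
from mandssm.synthetic import CohortSpec, generate_cohort
from mandssm.model import gpa_align, build_shape_matrix, fit_pca
from mandssm.evaluation import compactness, horn_parallel, spearman

meshes, truth = generate_cohort(CohortSpec(n_samples=200, n_points_base=900, seed=1))
aligned = gpa_align([np.asarray(m.vertices) for m in meshes])
matrix = build_shape_matrix(list(aligned))
model = fit_pca(matrix, k_max=20)

print(f"mode 1 explains {100*model.variance_fractions()[0]:.1f}% of variance")
print(f"compactness at k=3: {compactness(model)[2]:.4f}")
print(f"dominant modes (Horn): {horn_parallel(matrix, seed=2)}")
rs, p = spearman(truth.ages, model.weights[:, 0])
print(f"Spearman(age, mode-1 weight) = {rs:.3f} (p = {p:.1e})")
```

prints

```
mode 1 explains 79.1% of variance
compactness at k=3: 0.9998
dominant modes (Horn): 3
Spearman(age, mode-1 weight) = 0.914 (p = 2.5e-79)
```

— the growth mode dominates the spectrum (~4/5 of total variance), the
three planted modes are flagged as dominant and capture essentially all
variance, and the mode-1 weight recovers the planted age coupling.

The full analysis (cohort → reconstruction validation → registration →
model → evaluation → statistics) lives in `analysis/01...06`; each script
is a thin driver that prints what it found and writes tables under
`results/`. The staged pipeline is also exposed as a CLI:

```bash
mandssm synth   --out run --seed 1 --n-samples 50
mandssm template --out run
mandssm register --out run
mandssm build-ssm --out run
mandssm evaluate --out run
```

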