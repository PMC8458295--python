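"""Model-quality metrics and cohort statistics.

Compactness, leave-one-out generalization and specificity are the three
standard shape-model quality measures; Horn's parallel analysis determines
how many modes rise above size-matched noise. Spearman rank correlation
relates mode weights to dental age, and a two-way random-effects ICC
quantifies inter-observer agreement of mode weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import stats

from .geometry import MeshDistanceQuery
from .model import ShapeMatrix, ShapeModel, fit_pca, project_new_sample, synthesize

__all__ = [
    "EvaluationReport",
    "compactness",
    "generalization_loo",
    "specificity",
    "horn_parallel",
    "surface_distance_map",
    "spearman",
    "icc",
    "evaluate_model",
]


@dataclass
class EvaluationReport:
    compactness: np.ndarray       # cumulative variance fraction, index k-1
    generalization: np.ndarray    # mean mm error per retained-mode count
    specificity: np.ndarray       # mean mm distance per retained-mode count
    n_dominant: int               # Horn's parallel analysis

    def as_dict(self) -> dict:
        return {
            "compactness": self.compactness.tolist(),
            "generalization_mm": self.generalization.tolist(),
            "specificity_mm": self.specificity.tolist(),
            "n_dominant_modes": int(self.n_dominant),
        }


def compactness(model: ShapeModel) -> np.ndarray:
    """c(k) = cumulative fraction of total variance, k = 1..K."""
    if model.n_modes < 1:
        raise ValueError("model has no modes")
    lam = model.eigenvalues
    return np.cumsum(lam) / lam.sum()


def generalization_loo(
    mappings,
    k_max: int = 20,
    realign: bool = False,
    align_projection: bool = True,
) -> np.ndarray:
    """Leave-one-out generalization curve (mean point-to-point mm at each k).

    For every left-out sample the model is rebuilt on the remaining n-1
    shapes and the sample is reconstructed with k modes for k = 1..k_max.
    By default the alignment is kept fixed from the full cohort (each fold
    re-runs only the PCA); ``realign`` re-runs the Procrustes alignment per
    fold.
    """
    from .model import build_shape_matrix, gpa_align

    n = len(mappings)
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    errs = []
    for i in range(n):
        rest = [m for j, m in enumerate(mappings) if j != i]
        if realign:
            rest = gpa_align(rest)
        sub = build_shape_matrix(rest)
        model = fit_pca(sub, k_max=k_max)
        row = []
        for k in range(1, k_max + 1):
            kk = min(k, model.n_modes)  # kk = 0 degenerates to the mean shape
            _, _, err = project_new_sample(
                model, mappings[i], k=kk, align=align_projection
            )
            row.append(err)
        errs.append(row)
    return np.asarray(errs).mean(axis=0)


def specificity(
    model: ShapeModel,
    training: ShapeMatrix,
    n_draws: int = 1000,
    k: int | None = None,
    seed: int = 0,
) -> float:
    """Mean distance from random model instances to their nearest training shape.

    Draws standard-normal weights for the first k modes, synthesizes each
    instance, and records the mean point-to-point distance to the nearest
    member of the training set; returns the average over ``n_draws``.
    """
    k = model.n_modes if k is None else int(k)
    if k > model.n_modes:
        raise ValueError("k exceeds the number of model modes")
    rng = np.random.default_rng(seed)
    train = training.data.T.reshape(training.n_samples, -1, 3)
    total = 0.0
    for _ in range(n_draws):
        z = rng.standard_normal(k)
        inst = synthesize(model, z).reshape(-1, 3)
        d = np.linalg.norm(train - inst[None, :, :], axis=2).mean(axis=1)
        total += d.min()
    return total / n_draws


def specificity_curve(
    model: ShapeModel,
    training: ShapeMatrix,
    k_max: int = 20,
    n_draws: int = 200,
    seed: int = 0,
) -> np.ndarray:
    ks = range(1, min(k_max, model.n_modes) + 1)
    return np.array(
        [specificity(model, training, n_draws=n_draws, k=k, seed=seed + k) for k in ks]
    )


def horn_parallel(
    matrix: ShapeMatrix,
    n_sims: int = 25,
    percentile: float = 95.0,
    seed: int = 0,
    k_max: int | None = None,
) -> int:
    """Number of dominant modes by Horn's parallel analysis.

    Simulates ``n_sims`` matrices of i.i.d. Gaussian noise with the real
    matrix's dimensions, each row scaled to the real data's row variance,
    PCAs each through the dual trick, and counts how many real eigenvalues
    exceed the given percentile of the simulated eigenvalues of the same
    rank.
    """
    x = matrix.data
    n = x.shape[1]
    if n < 3:
        raise ValueError("parallel analysis needs at least 3 samples")
    rng = np.random.default_rng(seed)
    xc = x - x.mean(axis=1, keepdims=True)
    real = np.sort(np.linalg.eigvalsh(xc.T @ xc / (n - 1)))[::-1]
    row_sd = x.std(axis=1, ddof=1)
    sims = np.empty((n_sims, n))
    for s in range(n_sims):
        noise = rng.standard_normal(x.shape) * row_sd[:, None]
        nc = noise - noise.mean(axis=1, keepdims=True)
        sims[s] = np.sort(np.linalg.eigvalsh(nc.T @ nc / (n - 1)))[::-1]
    thresh = np.percentile(sims, percentile, axis=0)
    k_lim = len(real) if k_max is None else min(k_max, len(real))
    exceed = real[:k_lim] > thresh[:k_lim]
    # dominant modes are the leading run of eigenvalues above threshold
    # ("the first k modes exceed ..."); isolated later exceedances are the
    # expected false positives of the percentile rule
    below = np.flatnonzero(~exceed)
    return int(below[0]) if len(below) else int(k_lim)


def surface_distance_map(
    mesh_a: trimesh.Trimesh,
    mesh_b: trimesh.Trimesh,
    method: str = "ray-cast",
    signed: bool = False,
    cap_factor: float = 5.0,
) -> tuple[np.ndarray, dict]:
    """Per-vertex distance from mesh A to mesh B, plus summary statistics.

    ``ray-cast``: from each vertex of A along its (both-way) normal to the
    first intersection with B, falling back to the nearest surface point
    when no hit occurs within ``cap_factor`` x the mean edge length.
    ``nearest-point``: closest point on B's surface. ``signed`` flips the
    sign for vertices inside B (nearest-point mode measures sidedness by
    normal direction).
    """
    if method not in ("ray-cast", "nearest-point"):
        raise ValueError("method must be 'ray-cast' or 'nearest-point'")
    amin, amax = mesh_a.bounds
    bmin, bmax = mesh_b.bounds
    if np.any(amax < bmin) or np.any(bmax < amin):
        raise ValueError("meshes have disjoint bounding boxes")

    verts = np.asarray(mesh_a.vertices)
    normals = np.asarray(mesh_a.vertex_normals)
    query = MeshDistanceQuery(mesh_b)
    closest, d_near, _ = query.closest(verts)

    if method == "nearest-point":
        d = d_near.copy()
    else:
        cap = cap_factor * float(mesh_a.edges_unique_length.mean())
        t_fwd, hit_f = query.ray_first_hit(verts, normals, cap)
        t_bwd, hit_b = query.ray_first_hit(verts, -normals, cap)
        d = np.minimum(t_fwd, t_bwd)
        miss = ~np.isfinite(d)
        d[miss] = d_near[miss]

    if signed:
        side = np.einsum("ij,ij->i", verts - closest, normals)
        d = np.where(side < 0, -d, d)

    summary = {
        "mean": float(np.abs(d).mean()),
        "max": float(np.abs(d).max()),
        "signed_mean": float(d.mean()) if signed else None,
    }
    return d, summary


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("inputs must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def icc(ratings: np.ndarray, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is subjects x raters with no missing cells. Returns the ICC
    and its (1-alpha) confidence interval from the F-distribution method.
    A zero between-subject variance yields ICC = 0 (degenerate).
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[0] < 2 or r.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    if not np.all(np.isfinite(r)):
        raise ValueError("missing cells are not supported")
    n, k = r.shape
    grand = r.mean()
    row_m = r.mean(axis=1)
    col_m = r.mean(axis=0)
    ss_rows = k * ((row_m - grand) ** 2).sum()
    ss_cols = n * ((col_m - grand) ** 2).sum()
    ss_tot = ((r - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or msr <= mse:
        return 0.0, (0.0, 0.0)
    val = (msr - mse) / denom
    if mse <= 1e-30 * msr:  # perfect agreement: the F interval degenerates
        return float(val), (float(val), float(val))

    # McGraw & Wong F-based interval for ICC(A,1)
    a = k * val / (n * (1 - val))
    b = 1 + k * val * (n - 1) / (n * (1 - val))
    f_obs = msr / mse
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return float(val), (float(max(lower, -1.0)), float(min(upper, 1.0)))


def evaluate_model(
    model: ShapeModel,
    matrix: ShapeMatrix,
    mappings,
    k_max: int = 20,
    n_spec_draws: int = 200,
    seed: int = 0,
) -> EvaluationReport:
    """Assemble the full quality report for a fitted model."""
    k_eff = min(k_max, model.n_modes)
    return EvaluationReport(
        compactness=compactness(model)[:k_eff],
        generalization=generalization_loo(mappings, k_max=k_eff),
        specificity=specificity_curve(
            model, matrix, k_max=k_eff, n_draws=n_spec_draws, seed=seed
        ),
        n_dominant=horn_parallel(matrix, seed=seed),
    )
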