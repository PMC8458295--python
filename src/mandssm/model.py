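"""Statistical shape model core.

Corresponded semi-landmark sets are rigidly aligned by generalized Procrustes
analysis with six degrees of freedom (rotation + translation only, so the
size differences that carry growth survive into the model), stacked into a
shape matrix (one 3P-vector per sample), and decomposed by PCA. Mode weights
are expressed in standard-deviation units: the mean shape scores 0 on every
mode, and a weight of +-3 spans the plausible range of the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .correspondence import CorrespondenceMapping

__all__ = [
    "ShapeMatrix",
    "ShapeModel",
    "gpa_align",
    "build_shape_matrix",
    "fit_pca",
    "synthesize",
    "project_new_sample",
    "centroid_size",
    "save_model",
    "load_model",
]


def centroid_size(points: np.ndarray) -> float:
    """Root-sum-of-squares of distances to the centroid (classic size measure)."""
    c = points - points.mean(axis=0)
    return float(np.sqrt((c**2).sum()))


def _kabsch(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    h = src.T @ dst
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    return vt.T @ np.diag([1.0, 1.0, d]) @ u.T


@dataclass
class ShapeMatrix:
    """3P x n matrix of shape vectors (interleaved x1,y1,z1,...,xP,yP,zP)."""

    data: np.ndarray
    sample_ids: list[str]
    ages: np.ndarray

    def __post_init__(self):
        if self.data.ndim != 2 or self.data.shape[1] < 1:
            raise ValueError("shape matrix must be 2-D with >= 1 column")
        if self.data.shape[0] % 3:
            raise ValueError("shape-vector length must be divisible by 3")

    @property
    def n_points(self) -> int:
        return self.data.shape[0] // 3

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def column_points(self, j: int) -> np.ndarray:
        return self.data[:, j].reshape(-1, 3)


@dataclass
class ShapeModel:
    """Mean shape + orthonormal modes + eigenvalue spectrum + SD-unit weights."""

    mean_shape: np.ndarray          # (3P,)
    modes: np.ndarray               # (3P, K) orthonormal columns
    eigenvalues: np.ndarray         # (K,) descending, mm^2
    weights: np.ndarray             # (n, K) SD units
    n_samples: int
    sample_ids: list[str] = field(default_factory=list)
    ages: np.ndarray | None = None
    layout: str = "xyz-interleaved"

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    @property
    def n_points(self) -> int:
        return len(self.mean_shape) // 3

    def mean_points(self) -> np.ndarray:
        return self.mean_shape.reshape(-1, 3)

    def variance_fractions(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        return self.eigenvalues / tot if tot > 0 else np.zeros_like(self.eigenvalues)


def _as_points(m) -> np.ndarray:
    if isinstance(m, CorrespondenceMapping):
        return np.asarray(m.points, dtype=float)
    return np.asarray(m, dtype=float)


def gpa_align(
    mappings,
    tol: float = 1e-7,
    max_iter: int = 100,
) -> list:
    """Generalized Procrustes alignment with six degrees of freedom.

    Every shape is aligned to the evolving mean by optimal rotation
    (orthogonal Procrustes, det +1) and translation only — no scaling, so
    each output's centroid size equals its input's exactly. Iterates until
    the mean moves less than ``tol`` (mm, RMS per point). Returns objects of
    the same kind as the inputs (mappings keep their metadata).

    A ``warned`` attribute is set on the returned list when ``max_iter`` is
    reached without convergence.
    """
    if len(mappings) < 2:
        raise ValueError("GPA needs at least two shapes")
    pts = [_as_points(m) for m in mappings]
    p0 = pts[0].shape
    if any(p.shape != p0 for p in pts):
        raise ValueError("all shapes must share the same number of points")

    aligned = [p - p.mean(axis=0) for p in pts]
    mean = aligned[0].copy()
    objective: list[float] = []
    converged = False
    for _ in range(max_iter):
        for i, p in enumerate(aligned):
            rot = _kabsch(p, mean)
            aligned[i] = p @ rot.T
        new_mean = np.mean(aligned, axis=0)
        objective.append(float(np.mean([((a - new_mean) ** 2).sum() for a in aligned])))
        shift = float(np.sqrt(((new_mean - mean) ** 2).mean()))
        mean = new_mean
        if shift < tol:
            converged = True
            break

    out = []
    for m, p in zip(mappings, aligned):
        if isinstance(m, CorrespondenceMapping):
            o = CorrespondenceMapping(
                points=p,
                sample_id=m.sample_id,
                dental_age=m.dental_age,
                quality=m.quality,
                status=m.status,
            )
        else:
            o = p
        out.append(o)
    out = list(out)
    result = _GpaResult(out, objective, not converged)
    return result


class _GpaResult(list):
    """List of aligned shapes carrying the GPA objective trace."""

    def __init__(self, items, objective, warned):
        super().__init__(items)
        self.objective = objective
        self.warned = warned


def build_shape_matrix(aligned) -> ShapeMatrix:
    """Stack aligned mappings column-wise into the 3P x n shape matrix."""
    pts = [_as_points(m) for m in aligned]
    p0 = pts[0].shape
    if any(p.shape != p0 for p in pts):
        raise ValueError("mixed point counts in cohort")
    data = np.stack([p.reshape(-1) for p in pts], axis=1)
    ids = [
        m.sample_id if isinstance(m, CorrespondenceMapping) else f"S{i:04d}"
        for i, m in enumerate(aligned)
    ]
    ages = np.array(
        [
            m.dental_age if isinstance(m, CorrespondenceMapping) else np.nan
            for m in aligned
        ]
    )
    return ShapeMatrix(data=data, sample_ids=ids, ages=ages)


def fit_pca(matrix: ShapeMatrix, k_max: int = 20) -> ShapeModel:
    """PCA of the shape matrix through the n x n Gram (dual) problem.

    The mean shape vector is the column mean; the covariance (1/(n-1)
    normalization) is never materialized at 3P x 3P — its eigenvectors are
    obtained from the dual eigenproblem and lifted. Eigenvector signs are
    fixed by making the largest-magnitude component positive; per-sample
    weights are in SD units (w_ik = v_k . (x_i - mean) / sqrt(lambda_k)).
    """
    x = matrix.data
    n = x.shape[1]
    if n < 2:
        raise ValueError("PCA needs at least two samples")
    mean = x.mean(axis=1)
    xc = x - mean[:, None]
    gram = xc.T @ xc / (n - 1)
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]

    tot = float(np.trace(gram))
    keep = evals > max(tot * 1e-12, 1e-30)
    k = int(min(keep.sum(), n - 1, k_max))
    if k == 0:
        return ShapeModel(
            mean_shape=mean,
            modes=np.zeros((x.shape[0], 0)),
            eigenvalues=np.zeros(0),
            weights=np.zeros((n, 0)),
            n_samples=n,
            sample_ids=list(matrix.sample_ids),
            ages=matrix.ages,
        )
    evals = evals[:k]
    modes = xc @ evecs[:, :k] / np.sqrt((n - 1) * evals)[None, :]
    # deterministic sign: largest-magnitude component positive
    idx = np.abs(modes).argmax(axis=0)
    signs = np.sign(modes[idx, np.arange(k)])
    signs[signs == 0] = 1.0
    modes *= signs

    weights = (xc.T @ modes) / np.sqrt(evals)[None, :]
    return ShapeModel(
        mean_shape=mean,
        modes=modes,
        eigenvalues=evals,
        weights=weights,
        n_samples=n,
        sample_ids=list(matrix.sample_ids),
        ages=matrix.ages,
    )


def synthesize(model: ShapeModel, weights_sd: np.ndarray) -> np.ndarray:
    """Shape vector for the given SD-unit mode weights (zeros -> mean shape)."""
    w = np.asarray(weights_sd, dtype=float)
    if w.ndim != 1 or len(w) > model.n_modes:
        raise ValueError(f"weight vector longer than the model's {model.n_modes} modes")
    if not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite")
    k = len(w)
    return model.mean_shape + model.modes[:, :k] @ (w * np.sqrt(model.eigenvalues[:k]))


def project_new_sample(
    model: ShapeModel,
    mapping,
    k: int | None = None,
    align: bool = True,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Project an unseen corresponded shape onto the first k modes.

    The shape is first rigidly aligned (rotation + translation, 6 DOF) to
    the model mean (disable with ``align=False`` when the input is already
    expressed in the model frame), then its SD-unit weights, the
    reconstruction from those weights, and the mean point-to-point error
    (mm) are returned.
    """
    k = model.n_modes if k is None else int(k)
    if k > model.n_modes:
        raise ValueError(f"k={k} exceeds the model's {model.n_modes} modes")
    pts = _as_points(mapping)
    if pts.shape[0] != model.n_points:
        raise ValueError("mapping point count differs from the model's")
    mean_pts = model.mean_points()
    if align:
        mean_c = mean_pts - mean_pts.mean(axis=0)
        p = pts - pts.mean(axis=0)
        rot = _kabsch(p, mean_c)
        p = p @ rot.T + mean_pts.mean(axis=0)
    else:
        p = pts

    xc = p.reshape(-1) - model.mean_shape
    lam = model.eigenvalues[:k]
    w = (model.modes[:, :k].T @ xc) / np.sqrt(lam)
    recon = model.mean_shape + model.modes[:, :k] @ (w * np.sqrt(lam))
    err = float(
        np.linalg.norm((recon - p.reshape(-1)).reshape(-1, 3), axis=1).mean()
    )
    return w, recon, err


# ---------------------------------------------------------------------------
# persistence


def save_model(model: ShapeModel, path: str | Path) -> None:
    """Archive the model (npz) plus a CSV of weights and ages for stats."""
    path = Path(path)
    np.savez_compressed(
        path,
        mean_shape=model.mean_shape,
        modes=model.modes,
        eigenvalues=model.eigenvalues,
        weights=model.weights,
        n_samples=model.n_samples,
        sample_ids=np.asarray(model.sample_ids, dtype=object),
        ages=model.ages if model.ages is not None else np.full(model.n_samples, np.nan),
        layout=model.layout,
    )
    df = pd.DataFrame(
        model.weights, columns=[f"w{j + 1}" for j in range(model.n_modes)]
    )
    df.insert(0, "sample_id", model.sample_ids)
    df.insert(1, "age", model.ages if model.ages is not None else np.nan)
    df.to_csv(path.with_suffix(".weights.csv"), index=False)


def load_model(path: str | Path) -> ShapeModel:
    with np.load(Path(path), allow_pickle=True) as z:
        return ShapeModel(
            mean_shape=z["mean_shape"],
            modes=z["modes"],
            eigenvalues=z["eigenvalues"],
            weights=z["weights"],
            n_samples=int(z["n_samples"]),
            sample_ids=list(z["sample_ids"]),
            ages=z["ages"],
            layout=str(z["layout"]),
        )
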