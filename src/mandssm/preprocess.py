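"""Mesh preprocessing: uniform remeshing, dental-region leveling, mirroring.

`level_region` re-implements the manual "erase and fill" operation as an
automatic one: the selected patch (e.g. erupted teeth + alveolar bone) is
removed and each hole is filled with a minimal-curvature (harmonic) patch
re-triangulated to the local edge length. `mirror_symmetrize` builds the
fully symmetric template by keeping one half of a roughly bilateral mesh
and reflecting it across the (estimated or given) midsagittal plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from scipy.optimize import minimize
from scipy.sparse import lil_matrix
from scipy.sparse.linalg import spsolve
from scipy.spatial import Delaunay, cKDTree

from .geometry import sample_surface_points
from .remesh import remesh_uniform  # noqa: F401  (module surface)

__all__ = [
    "VertexSelection",
    "remesh_uniform",
    "level_region",
    "mirror_symmetrize",
    "estimate_symmetry_plane",
    "read_selection",
    "write_selection",
]


@dataclass
class VertexSelection:
    """A set of vertex indices with provenance (file or geometric predicate)."""

    indices: np.ndarray
    provenance: str = "geometric-predicate"

    def __post_init__(self):
        self.indices = np.unique(np.asarray(self.indices, dtype=int))

    def validate(self, mesh: trimesh.Trimesh) -> None:
        if len(self.indices) and (
            self.indices.min() < 0 or self.indices.max() >= len(mesh.vertices)
        ):
            raise ValueError("selection indices out of mesh bounds")


def read_selection(path: str | Path) -> VertexSelection:
    """Plain-text index list, one vertex id per line."""
    idx = np.loadtxt(path, dtype=int, ndmin=1)
    return VertexSelection(idx, provenance="manual-file")


def write_selection(sel: VertexSelection, path: str | Path) -> None:
    np.savetxt(path, sel.indices, fmt="%d")


# ---------------------------------------------------------------------------
# leveling


def _boundary_loops(faces: np.ndarray) -> list[list[int]]:
    """Ordered boundary loops (directed edges that appear exactly once)."""
    from collections import Counter

    directed = [(int(f[i]), int(f[(i + 1) % 3])) for f in faces for i in range(3)]
    undirected = Counter(tuple(sorted(e)) for e in directed)
    border = [e for e in directed if undirected[tuple(sorted(e))] == 1]
    succ = dict(border)
    loops = []
    seen = set()
    for start, _ in border:
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        nxt = succ[start]
        while nxt != start:
            loop.append(nxt)
            seen.add(nxt)
            nxt = succ[nxt]
        loops.append(loop)
    return loops


def _fill_hole(
    verts: np.ndarray, loop: list[int], spacing: float
) -> tuple[np.ndarray, np.ndarray]:
    """Harmonic patch over one hole.

    The loop is mapped to a circle by cumulative arc length; interior sample
    points are laid out on a polar grid at roughly ``spacing``; the 2-D
    Delaunay triangulation (boundary on the convex hull, so every boundary
    edge is kept) provides connectivity; interior 3-D positions solve the
    uniform-weight Laplace equation with the loop fixed. Returns
    (interior_points (m,3), patch_faces indexing [loop..., interior...]).
    """
    pts = verts[loop]
    n = len(loop)
    seg = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=0 if False else 1)
    arc = np.concatenate([[0.0], np.cumsum(seg[:-1])])
    total = seg.sum()
    ang = 2.0 * np.pi * arc / total
    radius = total / (2.0 * np.pi)
    bnd2d = radius * np.stack([np.cos(ang), np.sin(ang)], axis=1)

    interior2d = []
    n_rings = max(int(np.floor(radius / spacing)), 0)
    for ri in range(1, n_rings + 1):
        r = radius * (1.0 - ri * spacing / radius)
        if r < 0.35 * spacing:
            break
        n_th = max(int(round(2.0 * np.pi * r / spacing)), 4)
        th = 2.0 * np.pi * np.arange(n_th) / n_th + 0.5 * ri
        interior2d.append(r * np.stack([np.cos(th), np.sin(th)], axis=1))
    if radius > 0.7 * spacing and n_rings > 0:
        interior2d.append(np.zeros((1, 2)))
    interior2d = np.concatenate(interior2d, axis=0) if interior2d else np.zeros((0, 2))

    all2d = np.concatenate([bnd2d, interior2d], axis=0)
    tri = Delaunay(all2d)
    simplices = tri.simplices
    # drop caps outside the (convex) circle region: none needed; but drop
    # triangles formed purely by consecutive boundary points that are
    # degenerate in 2-D
    e1 = all2d[simplices[:, 1]] - all2d[simplices[:, 0]]
    e2 = all2d[simplices[:, 2]] - all2d[simplices[:, 0]]
    areas = np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
    simplices = simplices[areas > 1e-12]

    m = len(interior2d)
    if m == 0:
        return np.zeros((0, 3)), simplices

    # uniform-weight Laplace solve for interior 3-D positions
    n_all = n + m
    lap = lil_matrix((m, m))
    rhs = np.zeros((m, 3))
    nbrs: list[set] = [set() for _ in range(n_all)]
    for s in simplices:
        for i in range(3):
            a, b = s[i], s[(i + 1) % 3]
            nbrs[a].add(b)
            nbrs[b].add(a)
    for i in range(m):
        gi = n + i
        deg = len(nbrs[gi])
        lap[i, i] = deg
        for v in nbrs[gi]:
            if v >= n:
                lap[i, v - n] = -1.0
            else:
                rhs[i] += pts[v]
    interior3d = np.column_stack(
        [spsolve(lap.tocsr(), rhs[:, c]) for c in range(3)]
    )
    return interior3d, simplices


def level_region(mesh: trimesh.Trimesh, selection: VertexSelection) -> trimesh.Trimesh:
    """Remove the selected patch and fill each hole with a harmonic patch.

    Non-selected vertices are preserved bit-identically; a planar hole
    boundary yields a planar fill.
    """
    selection.validate(mesh)
    if len(selection.indices) == 0:
        return mesh.copy()
    if len(selection.indices) >= len(mesh.vertices):
        raise ValueError("selection covers the whole mesh")

    verts = np.asarray(mesh.vertices)
    faces = np.asarray(mesh.faces)
    selected = np.zeros(len(verts), dtype=bool)
    selected[selection.indices] = True
    keep_face = ~selected[faces].any(axis=1)
    kept_faces = faces[keep_face]
    if len(kept_faces) == 0:
        raise ValueError("selection covers the whole mesh surface")

    loops = _boundary_loops(kept_faces)
    el = mesh.edges_unique_length
    spacing = float(el.mean())

    new_vert_blocks = [verts]
    new_face_blocks = [kept_faces]
    next_idx = len(verts)
    kept_directed = {
        (int(f[i]), int(f[(i + 1) % 3])) for f in kept_faces for i in range(3)
    }
    for loop in loops:
        interior, patch = _fill_hole(verts, loop, spacing)
        index_map = np.concatenate(
            [np.asarray(loop, dtype=np.int64), next_idx + np.arange(len(interior))]
        )
        patch_global = index_map[patch]
        # orient the patch opposite to the kept faces along the boundary
        flip = False
        for f in patch_global:
            for i in range(3):
                e = (int(f[i]), int(f[(i + 1) % 3]))
                if e in kept_directed:
                    flip = True
                    break
                if (e[1], e[0]) in kept_directed:
                    break
            else:
                continue
            break
        if flip:
            patch_global = patch_global[:, ::-1]
        new_vert_blocks.append(interior)
        new_face_blocks.append(patch_global)
        next_idx += len(interior)

    all_verts = np.concatenate(new_vert_blocks, axis=0)
    all_faces = np.concatenate(new_face_blocks, axis=0)
    used = np.unique(all_faces)
    remap = np.full(len(all_verts), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    out = trimesh.Trimesh(
        vertices=all_verts[used], faces=remap[all_faces], process=False
    )
    out.metadata["kept_original"] = used[used < len(verts)]
    return out


# ---------------------------------------------------------------------------
# mirroring


def _reflect(points: np.ndarray, origin: np.ndarray, normal: np.ndarray) -> np.ndarray:
    d = (points - origin) @ normal
    return points - 2.0 * d[:, None] * normal


def _misfit(points: np.ndarray, tree: cKDTree, origin, normal) -> float:
    return float(tree.query(_reflect(points, origin, normal))[0].mean())


def estimate_symmetry_plane(
    mesh: trimesh.Trimesh, n_samples: int = 1500, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Estimate the midsagittal plane: (origin, unit normal, mean misfit mm).

    Candidates are the principal axes through the centroid; the best is
    refined by direct minimization of the reflection-ICP misfit (mean
    nearest-neighbor distance of the reflected sample cloud).
    """
    pts = sample_surface_points(mesh, n_samples, seed=seed)
    dense = sample_surface_points(mesh, 6 * n_samples, seed=seed + 1)
    tree = cKDTree(dense)
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    _, axes = np.linalg.eigh(cov)
    best = min(
        (ax for ax in axes.T),
        key=lambda ax: _misfit(pts, tree, centroid, ax / np.linalg.norm(ax)),
    )
    best = best / np.linalg.norm(best)

    def pack(n0):
        th0 = np.arccos(np.clip(n0[2], -1, 1))
        ph0 = np.arctan2(n0[1], n0[0])
        return th0, ph0

    th0, ph0 = pack(best)

    def cost(p):
        th, ph, off = p
        n = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
        return _misfit(pts, tree, centroid + off * n, n)

    res = minimize(cost, [th0, ph0, 0.0], method="Nelder-Mead",
                   options={"xatol": 1e-5, "fatol": 1e-9, "maxiter": 400})
    th, ph, off = res.x
    normal = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
    origin = centroid + off * normal
    # report the exact point-to-surface misfit (the k-d-tree chamfer value
    # used during optimization carries a sampling-noise floor)
    from .geometry import MeshDistanceQuery

    misfit = float(MeshDistanceQuery(mesh).distances(_reflect(pts, origin, normal)).mean())
    return origin, normal, misfit


def mirror_symmetrize(
    mesh: trimesh.Trimesh,
    plane: tuple[np.ndarray, np.ndarray] | None = None,
    keep: str = "left",
    misfit_tolerance: float = 0.05,
) -> trimesh.Trimesh:
    """Keep one half, reflect it across the midsagittal plane, stitch.

    ``keep`` selects which side survives ('left' = negative side of the
    plane normal). Output is exactly symmetric under the reflection. If no
    plane is given it is estimated; an estimated misfit above
    ``misfit_tolerance`` x (bounding-box diagonal) aborts (no plausible
    symmetry).
    """
    if keep not in ("left", "right"):
        raise ValueError("keep must be 'left' or 'right'")
    diag = float(np.linalg.norm(mesh.extents))
    if plane is None:
        origin, normal, misfit = estimate_symmetry_plane(mesh)
        if misfit > misfit_tolerance * diag:
            raise ValueError(
                f"no plausible symmetry plane (misfit {misfit:.3f} mm)"
            )
    else:
        origin = np.asarray(plane[0], dtype=float)
        normal = np.asarray(plane[1], dtype=float)
        normal = normal / np.linalg.norm(normal)

    side = normal if keep == "right" else -normal
    half = trimesh.intersections.slice_mesh_plane(
        mesh, plane_normal=side, plane_origin=origin
    )
    verts = np.asarray(half.vertices, dtype=float).copy()
    # snap cut-boundary vertices exactly onto the plane
    d = (verts - origin) @ normal
    on_plane = np.abs(d) < 1e-6 * max(diag, 1.0)
    verts[on_plane] -= d[on_plane, None] * normal

    faces = np.asarray(half.faces, dtype=np.int64)
    n_half = len(verts)
    off_plane = ~on_plane
    mirror_map = np.empty(n_half, dtype=np.int64)
    mirror_map[on_plane] = np.flatnonzero(on_plane)
    mirror_map[off_plane] = n_half + np.arange(off_plane.sum())
    mirrored = _reflect(verts[off_plane], origin, normal)
    all_verts = np.concatenate([verts, mirrored], axis=0)
    all_faces = np.concatenate([faces, mirror_map[faces][:, ::-1]], axis=0)
    out = trimesh.Trimesh(vertices=all_verts, faces=all_faces, process=False)
    out.merge_vertices(merge_tex=True, merge_norm=True)
    if out.volume < 0:
        out.invert()
    out.metadata["symmetry_plane"] = (origin, normal)
    return out
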