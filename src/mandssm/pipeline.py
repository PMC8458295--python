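"""Pipeline orchestration: staged, manifest-driven, reproducible.

Each stage reads and writes plain artifacts under the output directory
(ASCII PLY meshes, CSV manifests, an npz model container, JSON reports) and
records a run log with the configuration hash, so a rerun with the same
config and seed reproduces the same artifacts.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from . import __version__
from .correspondence import CpdStage, map_template, refine_template
from .evaluation import evaluate_model, spearman
from .model import (
    build_shape_matrix,
    fit_pca,
    gpa_align,
    save_model,
)
from .preprocess import mirror_symmetrize, remesh_uniform
from .reconstruct import ReconstructionParams, reconstruct_mesh
from .synthetic import CohortSpec, generate_cohort, rasterize_mesh

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

COMMANDS = (
    "synth",
    "reconstruct",
    "preprocess",
    "template",
    "register",
    "build-ssm",
    "evaluate",
    "stats",
    "all",
)


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    k_max: int = 20

    # cohort generation
    cohort: dict = field(default_factory=dict)

    # voxelization / reconstruction
    raster_spacing: tuple = (0.4, 0.4, 1.0)
    raster_pad: float = 3.0
    reconstruction: dict = field(default_factory=dict)

    # template construction
    template_points: int = 700
    mirror_template: bool = True

    # registration
    stages: list = field(
        default_factory=lambda: [[2.0, 3.0, 0.1], [1.5, 2.0, 0.1], [1.0, 1.0, 0.1]]
    )
    quality_mm: float = 0.5
    refine_samples: int = 0       # 0 disables template refinement
    refine_iterations: int = 1

    # evaluation
    n_spec_draws: int = 200

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(**{"seed": self.seed, **self.cohort})

    def cpd_stages(self) -> list[CpdStage]:
        return [CpdStage(beta=b, lam=l, w=w) for b, l, w in self.stages]

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(**data)


def _write_ply_points(points: np.ndarray, path: Path) -> None:
    with open(path, "w") as f:
        f.write("ply\nformat ascii 1.0\n")
        f.write(f"element vertex {len(points)}\n")
        f.write("property float x\nproperty float y\nproperty float z\n")
        f.write("end_header\n")
        for p in points:
            f.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


def _read_ply_points(path: Path) -> np.ndarray:
    mesh = trimesh.load(str(path), process=False)
    return np.asarray(mesh.vertices, dtype=float)


def _log(out: Path, stage: str, payload: dict) -> None:
    log_path = out / "run_log.json"
    log = json.loads(log_path.read_text()) if log_path.exists() else {}
    log[stage] = {"time": time.strftime("%Y-%m-%d %H:%M:%S"), **payload}
    log_path.write_text(json.dumps(log, indent=2, default=str))


class PipelineError(RuntimeError):
    pass


def _require(path: Path, producer: str):
    if not path.exists():
        raise PipelineError(
            f"missing artifact {path.name}: run the '{producer}' command first"
        )


def run_pipeline(config: PipelineConfig, command: str) -> dict:
    """Execute one pipeline stage (or 'all'); returns a result summary."""
    if command not in COMMANDS:
        raise ValueError(f"unknown command {command!r}; choose from {COMMANDS}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    if command == "all":
        result = {}
        for cmd in ("synth", "template", "register", "build-ssm", "evaluate", "stats"):
            result[cmd] = run_pipeline(config, cmd)
        return result

    if command == "synth":
        spec = config.cohort_spec()
        meshes, truth = generate_cohort(spec)
        mesh_dir = out / "meshes"
        mesh_dir.mkdir(exist_ok=True)
        rows = []
        for m in meshes:
            sid = m.metadata["sample_id"]
            path = mesh_dir / f"{sid}.ply"
            m.export(str(path), encoding="ascii")
            rows.append({"sample_id": sid, "age": m.metadata["dental_age"],
                         "mesh": str(path), "status": "ok"})
        pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
        k = truth.true_weights.shape[1]
        gt = pd.DataFrame(truth.true_weights, columns=[f"w{j+1}" for j in range(k)])
        gt.insert(0, "sample_id", [r["sample_id"] for r in rows])
        gt.insert(1, "age", truth.ages)
        gt.to_csv(out / "ground_truth.csv", index=False)
        np.savez_compressed(out / "ground_truth_modes.npz",
                            mode_fields=truth.mode_fields, mode_sds=truth.mode_sds,
                            base_vertices=truth.base_vertices,
                            landmark_ids=json.dumps(truth.landmark_ids))
        _log(out, "synth", {"config_hash": chash, "version": __version__,
                            "n_samples": len(meshes)})
        return {"n_samples": len(meshes)}

    if command == "reconstruct":
        _require(out / "manifest.csv", "synth")
        manifest = pd.read_csv(out / "manifest.csv")
        params = ReconstructionParams(**config.reconstruction)
        rec_dir = out / "recon"
        rec_dir.mkdir(exist_ok=True)
        statuses = {}
        for _, row in manifest.iterrows():
            mesh = trimesh.load(row["mesh"], process=False)
            vol = rasterize_mesh(mesh, config.raster_spacing, pad=config.raster_pad)
            rec = reconstruct_mesh(vol, params)
            path = rec_dir / f"{row['sample_id']}.ply"
            rec.export(str(path), encoding="ascii")
            statuses[row["sample_id"]] = "ok"
        _log(out, "reconstruct", {"config_hash": chash, "samples": statuses})
        return {"n_reconstructed": len(statuses)}

    if command == "preprocess" or command == "template":
        _require(out / "manifest.csv", "synth")
        manifest = pd.read_csv(out / "manifest.csv")
        first = trimesh.load(manifest.iloc[0]["mesh"], process=False)
        tpl_mesh = first
        if config.mirror_template:
            tpl_mesh = mirror_symmetrize(tpl_mesh)
        tpl_mesh = remesh_uniform(tpl_mesh, config.template_points)
        tpl_mesh.export(str(out / "template.ply"), encoding="ascii")
        template = np.asarray(tpl_mesh.vertices)
        if config.refine_samples > 0:
            meshes = [trimesh.load(p, process=False) for p in manifest["mesh"]]
            template = refine_template(
                template,
                meshes,
                n_samples_used=min(config.refine_samples, len(meshes)),
                n_iterations=config.refine_iterations,
                stages=config.cpd_stages(),
                quality_threshold=config.quality_mm,
                seed=config.seed,
            )
        _write_ply_points(template, out / "template_points.ply")
        _log(out, "template", {"config_hash": chash, "P": len(template)})
        return {"P": len(template)}

    if command == "register":
        _require(out / "manifest.csv", "synth")
        _require(out / "template_points.ply", "template")
        manifest = pd.read_csv(out / "manifest.csv")
        template = _read_ply_points(out / "template_points.ply")
        map_dir = out / "mappings"
        map_dir.mkdir(exist_ok=True)
        stages = config.cpd_stages()
        qualities, statuses = [], []
        for i, row in manifest.iterrows():
            mesh = trimesh.load(row["mesh"], process=False)
            mp = map_template(
                template,
                mesh,
                stages=stages,
                quality_threshold=config.quality_mm,
                sample_id=row["sample_id"],
                dental_age=row["age"],
                seed=config.seed + 17 * i,
            )
            _write_ply_points(mp.points, map_dir / f"{row['sample_id']}.ply")
            qualities.append(mp.quality)
            statuses.append(mp.status)
        manifest["quality"] = qualities
        manifest["status"] = statuses
        manifest.to_csv(out / "manifest.csv", index=False)
        n_ok = sum(s == "ok" for s in statuses)
        _log(out, "register", {"config_hash": chash, "n_ok": n_ok,
                               "n_failed": len(statuses) - n_ok,
                               "failed": [s for s, st in zip(manifest['sample_id'], statuses) if st != 'ok']})
        return {"n_ok": n_ok, "n_total": len(statuses),
                "success_rate": n_ok / len(statuses)}

    if command == "build-ssm":
        _require(out / "manifest.csv", "synth")
        manifest = pd.read_csv(out / "manifest.csv")
        if "status" not in manifest or "quality" not in manifest:
            raise PipelineError("manifest lacks registration results: run 'register'")
        ok = manifest[manifest["status"] == "ok"]
        from .correspondence import CorrespondenceMapping

        mappings = [
            CorrespondenceMapping(
                points=_read_ply_points(out / "mappings" / f"{r.sample_id}.ply"),
                sample_id=r.sample_id,
                dental_age=r.age,
                quality=r.quality,
            )
            for r in ok.itertuples()
        ]
        aligned = gpa_align(mappings)
        matrix = build_shape_matrix(aligned)
        model = fit_pca(matrix, k_max=config.k_max)
        save_model(model, out / "model.npz")
        np.savez_compressed(out / "shape_matrix.npz", data=matrix.data,
                            sample_ids=np.asarray(matrix.sample_ids, dtype=object),
                            ages=matrix.ages)
        _log(out, "build-ssm", {"config_hash": chash, "n_used": len(mappings),
                                "n_modes": model.n_modes})
        return {"n_modes": model.n_modes, "n_used": len(mappings)}

    if command == "evaluate":
        _require(out / "model.npz", "build-ssm")
        _require(out / "shape_matrix.npz", "build-ssm")
        from .model import ShapeMatrix, load_model

        model = load_model(out / "model.npz")
        with np.load(out / "shape_matrix.npz", allow_pickle=True) as z:
            matrix = ShapeMatrix(z["data"], list(z["sample_ids"]), z["ages"])
        mappings = [matrix.column_points(j) for j in range(matrix.n_samples)]
        report = evaluate_model(
            model, matrix, mappings, k_max=config.k_max,
            n_spec_draws=config.n_spec_draws, seed=config.seed,
        )
        (out / "evaluation.json").write_text(json.dumps(report.as_dict(), indent=2))
        k = len(report.compactness)
        pd.DataFrame({
            "k": np.arange(1, k + 1),
            "compactness": report.compactness,
            "generalization_mm": report.generalization[:k],
            "specificity_mm": report.specificity[:k],
        }).to_csv(out / "evaluation_curves.csv", index=False)
        _log(out, "evaluate", {"config_hash": chash,
                               "n_dominant": report.n_dominant})
        return report.as_dict()

    if command == "stats":
        _require(out / "model.npz", "build-ssm")
        from .model import load_model

        model = load_model(out / "model.npz")
        rows = []
        for j in range(model.n_modes):
            rs, p = spearman(model.ages, model.weights[:, j])
            rows.append({"mode": j + 1, "spearman_r": rs, "p_value": p})
        df = pd.DataFrame(rows)
        df.to_csv(out / "age_correlations.csv", index=False)
        _log(out, "stats", {"config_hash": chash,
                            "mode1_spearman": rows[0]["spearman_r"]})
        return {"mode1_spearman": rows[0]["spearman_r"]}

    raise AssertionError("unreachable")
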