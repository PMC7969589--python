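"""End-to-end study orchestration: segment -> mesh -> clean/smooth/decimate ->
align -> atlas -> statistics -> maps, driven by a :class:`StudyConfig`, with
stage-level logging, cached/resumable outputs and a JSON manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import atlas as _atlas
from . import maps as _maps
from . import shapestats as _stats
from .errors import PipelineError
from .landmarks import fit_similarity, read_landmarks
from .mesh import TriMesh, centroid_size, clean_mesh, decimate, laplacian_smooth, read_mesh, write_mesh
from .volume import extract_surface, largest_component, morph_open_close, read_volume, threshold_mask

logger = logging.getLogger("meshmorph.pipeline")

__all__ = ["StudyConfig", "run_pipeline"]


@dataclass
class StudyConfig:
    """Parameters of a full landmark-free study.

    Inputs are either a directory of volumes (``volume_dir``) to segment and
    mesh, or a directory of pre-made meshes (``mesh_dir``).  ``labels_csv``
    (columns ``subject, group``) enables the group statistics and maps.

    Alignment: ``"none"`` uses meshes as-is, ``"centroid"`` centres them
    (rigid-branch analogue), ``"centroid-scale"`` additionally normalises
    centroid size, ``"landmark-rigid"`` / ``"landmark-similarity"`` align
    each subject's landmark file in ``landmark_dir`` to the first subject's.
    Shape statistics conventionally run on the scaled branch and stretch
    maps on the unscaled one.
    """

    out_dir: str
    mesh_dir: str | None = None
    volume_dir: str | None = None
    labels_csv: str | None = None
    landmark_dir: str | None = None
    # segmentation
    tau: float = 0.5
    open_close_radius: int = 0
    keep_largest: bool = True
    # mesh preprocessing
    merge_tol: float = 1e-6
    smooth_iterations: int = 0
    smooth_lam: float = 0.5
    decimate_fraction: float = 1.0
    # alignment
    alignment: str = "none"
    # atlas
    sigma_w: float = 0.5
    sigma_v: float | None = None
    sigma_eps: float | None = None
    n_timesteps: int = 10
    max_iter: int = 150
    atlas_mode: str = "varifold"
    # statistics
    pca_dim: int = 5
    k_folds: int = 5
    n_perm: int = 1000
    n_scrambles: int = 1000
    seed: int = 0
    resume: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        cfg = json.loads(Path(path).read_text())
        return cls(**cfg)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _stage(manifest: list[dict], name: str, inputs, outputs, params, t0: float) -> None:
    entry = {
        "stage": name,
        "inputs": inputs,
        "outputs": outputs,
        "parameters": params,
        "wall_time_s": round(time.perf_counter() - t0, 4),
    }
    manifest.append(entry)
    logger.info("stage %-12s %6.2fs  params=%s", name, entry["wall_time_s"], params)


def run_pipeline(config: StudyConfig) -> dict:
    """Execute the configured stages and return the manifest (also written to
    ``out_dir/manifest.json``).

    Fails fast, naming the stage, when a stage input is missing; outputs of
    completed stages are preserved on later failures, and existing stage
    outputs are reused when ``resume`` is on.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []

    # ---- stage: acquire meshes (segment volumes or read pre-made meshes)
    t0 = time.perf_counter()
    subject_ids: list[str] = []
    meshes: list[TriMesh] = []
    if config.volume_dir is not None:
        vdir = Path(config.volume_dir)
        if not vdir.is_dir():
            raise PipelineError(f"stage 'segment': volume_dir {vdir} does not exist")
        vol_paths = sorted(
            p for p in vdir.iterdir() if p.suffix.lower() in {".nrrd", ".nii", ".gz", ".mhd"}
        )
        if not vol_paths:
            raise PipelineError(f"stage 'segment': no volumes found in {vdir}")
        seg_dir = out / "meshes_raw"
        seg_dir.mkdir(exist_ok=True)
        for p in vol_paths:
            sid = p.name.split(".")[0]
            dst = seg_dir / f"{sid}.ply"
            if config.resume and dst.exists():
                meshes.append(read_mesh(dst))
            else:
                vol = read_volume(p)
                mask = threshold_mask(vol, config.tau)
                if config.open_close_radius >= 1:
                    mask = morph_open_close(mask, config.open_close_radius)
                if config.keep_largest:
                    mask = largest_component(mask)
                mesh = extract_surface(mask)
                write_mesh(mesh, dst)
                meshes.append(mesh)
            subject_ids.append(sid)
        _stage(manifest, "segment", [str(p) for p in vol_paths], [str(seg_dir)],
               {"tau": config.tau, "open_close_radius": config.open_close_radius}, t0)
    elif config.mesh_dir is not None:
        mdir = Path(config.mesh_dir)
        if not mdir.is_dir():
            raise PipelineError(f"stage 'load': mesh_dir {mdir} does not exist")
        mesh_paths = sorted(
            p for p in mdir.iterdir() if p.suffix.lower() in {".ply", ".obj", ".stl"}
        )
        if not mesh_paths:
            raise PipelineError(f"stage 'load': no meshes found in {mdir}")
        for p in mesh_paths:
            subject_ids.append(p.stem)
            meshes.append(read_mesh(p))
        _stage(manifest, "load", [str(p) for p in mesh_paths], [], {}, t0)
    else:
        raise PipelineError("stage 'load': config needs mesh_dir or volume_dir")

    # ---- stage: clean / smooth / decimate
    t0 = time.perf_counter()
    pre_dir = out / "meshes_pre"
    pre_dir.mkdir(exist_ok=True)
    processed = []
    for sid, mesh in zip(subject_ids, meshes):
        dst = pre_dir / f"{sid}.ply"
        if config.resume and dst.exists():
            processed.append(read_mesh(dst))
            continue
        m = clean_mesh(mesh, config.merge_tol)
        if config.smooth_iterations > 0:
            m = laplacian_smooth(m, config.smooth_iterations, config.smooth_lam)
        if config.decimate_fraction < 1.0:
            m = decimate(m, config.decimate_fraction)
        write_mesh(m, dst)
        processed.append(m)
    meshes = processed
    _stage(manifest, "preprocess", [], [str(pre_dir)],
           {"merge_tol": config.merge_tol, "smooth_iterations": config.smooth_iterations,
            "decimate_fraction": config.decimate_fraction}, t0)

    # ---- stage: alignment
    t0 = time.perf_counter()
    mode = config.alignment
    if mode not in {"none", "centroid", "centroid-scale", "landmark-rigid", "landmark-similarity"}:
        raise PipelineError(f"stage 'align': unknown alignment mode {mode!r}")
    if mode.startswith("landmark"):
        if config.landmark_dir is None:
            raise PipelineError(
                f"stage 'align': alignment={mode!r} requires landmark files (landmark_dir unset)"
            )
        ldir = Path(config.landmark_dir)
        lm_sets = {}
        for sid in subject_ids:
            cands = list(ldir.glob(f"{sid}.*"))
            if not cands:
                raise PipelineError(f"stage 'align': no landmark file for subject {sid} in {ldir}")
            lm_sets[sid] = read_landmarks(cands[0])
        ref = lm_sets[subject_ids[0]]
        aligned = []
        for sid, mesh in zip(subject_ids, meshes):
            T = fit_similarity(lm_sets[sid], ref, allow_scale=mode.endswith("similarity"))
            aligned.append(TriMesh(T.apply(mesh.vertices), mesh.faces.copy()))
        meshes = aligned
    elif mode in {"centroid", "centroid-scale"}:
        sizes = [centroid_size(m.vertices).centroid_size for m in meshes]
        mean_cs = float(np.mean(sizes))
        aligned = []
        for mesh, cs in zip(meshes, sizes):
            v = mesh.vertices - mesh.vertices.mean(axis=0)
            if mode == "centroid-scale":
                v = v * (mean_cs / cs)
            aligned.append(TriMesh(v, mesh.faces.copy()))
        meshes = aligned
    _stage(manifest, "align", [], [], {"alignment": mode}, t0)

    # ---- stage: atlas
    t0 = time.perf_counter()
    atlas_dir = out / "atlas"
    params = _atlas.KernelParams(
        sigma_W=config.sigma_w, sigma_V=config.sigma_v, sigma_eps=config.sigma_eps,
        n_timesteps=config.n_timesteps, max_iter=config.max_iter, mode=config.atlas_mode,
    )
    if config.resume and (atlas_dir / "momenta.txt").exists():
        model = _atlas.load_atlas(atlas_dir)
    else:
        model = _atlas.estimate_atlas(meshes, params, subject_ids=subject_ids)
        _atlas.save_atlas(model, atlas_dir)
    _stage(manifest, "atlas", [str(pre_dir)], [str(atlas_dir)],
           {"sigma_w": config.sigma_w, "sigma_v": params.sigma_V,
            "sigma_eps": params.sigma_eps, "n_cp": model.control_points.n}, t0)

    # ---- stage: statistics (needs group labels)
    labels = None
    if config.labels_csv is not None:
        lpath = Path(config.labels_csv)
        if not lpath.exists():
            raise PipelineError(f"stage 'stats': labels_csv {lpath} does not exist")
        df = pd.read_csv(lpath).set_index("subject")
        try:
            labels = df.loc[subject_ids, "group"].to_numpy()
        except KeyError as exc:
            raise PipelineError(f"stage 'stats': subject missing from labels_csv: {exc}") from exc
    results: dict = {}
    if labels is not None and len(np.unique(labels)) == 2:
        t0 = time.perf_counter()
        feats = model.momenta.as_features(subject_ids)
        sc = _stats.kernel_pca(feats, dim=config.pca_dim)
        perm = _stats.classify_permutation_test(
            sc, labels, k_folds=config.k_folds, n_perm=config.n_perm, seed=config.seed
        )
        scramble = _stats.scrambled_group_test(
            sc, labels, n_scrambles=config.n_scrambles, seed=config.seed + 1
        )
        results = {
            "cv_accuracy": perm.observed_score,
            "permutation_p": perm.p_value,
            "scramble_z": scramble.z_score,
            "scramble_shapiro_p": scramble.shapiro_p,
            "explained_variance_ratio": sc.explained_variance_ratio.tolist(),
        }
        pd.DataFrame(
            sc.scores, index=subject_ids,
            columns=[f"PC{i + 1}" for i in range(sc.dim)],
        ).to_csv(out / "scores.csv")
        (out / "stats.json").write_text(json.dumps(results, indent=2) + "\n")
        _stage(manifest, "stats", [str(atlas_dir)], [str(out / "stats.json")],
               {"pca_dim": config.pca_dim, "k_folds": config.k_folds,
                "n_perm": config.n_perm, "seed": config.seed}, t0)

        # ---- stage: maps (group means, displacement + stretch heatmaps)
        t0 = time.perf_counter()
        maps_dir = out / "maps"
        maps_dir.mkdir(exist_ok=True)
        ga, gb = np.unique(labels)
        ids = np.asarray(subject_ids)
        mean_a = _atlas.group_mean_mesh(model, list(ids[labels == ga]))
        mean_b = _atlas.group_mean_mesh(model, list(ids[labels == gb]))
        write_mesh(mean_a, maps_dir / f"mean_{ga}.ply")
        write_mesh(mean_b, maps_dir / f"mean_{gb}.ply")
        disp = _maps.displacement_map(mean_a, mean_b)
        stretch = _maps.stretch_map(mean_a, mean_b)
        _maps.write_vertex_map(disp, maps_dir / "displacement.ply", maps_dir / "displacement.csv")
        _maps.write_vertex_map(stretch, maps_dir / "stretch.ply", maps_dir / "stretch.csv")
        results["max_displacement"] = float(disp.values.max())
        _stage(manifest, "maps", [str(atlas_dir)], [str(maps_dir)], {}, t0)

    doc = {"stages": manifest, "results": results, "subjects": subject_ids}
    (out / "manifest.json").write_text(json.dumps(doc, indent=2) + "\n")
    return doc
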