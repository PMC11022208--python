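"""End-to-end pipeline orchestration with a reproducible artifact manifest.

Stages: phantom (or user-supplied CT + kidney mask) -> preprocess ->
extract -> mesh -> skeletonize -> trajectory -> render -> metrics.  Every
run writes the resolved config next to its outputs and a ``manifest.json``
listing each produced file with its SHA-256 and the stage parameters that
made it.  Stages are resumable: outputs already on disk are not recomputed,
and because every stage is deterministic under the run seed, regenerated
outputs are byte-identical.

Timings are logged to stderr only — the manifest contains nothing
run-dependent besides the configuration itself.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from . import extraction, meshing, volumes
from . import skeleton as skel_mod
from .render import PRESETS, CameraPose
from .render import render as render_frame
from .render import sample_trajectory
from .metrics import RandomProjectionExtractor, kid
from .phantom import PhantomSpec, make_phantom, make_style_domain

__all__ = ["default_config", "run_pipeline", "PipelineError"]

log = logging.getLogger("uroscope.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def default_config() -> dict:
    return {
        "seed": 0,
        "outdir": "uroscope_run",
        "inputs": {  # set ct/kidney_mask paths to skip the phantom stage
            "ct": None,
            "kidney_mask": None,
        },
        "phantom": {
            "grid_shape": [128, 128, 128],
            "n_calyces": 6,
            "noise_sd": 20.0,
        },
        "preprocess": {"clip": [-256.0, 512.0], "resample_shape": None},
        "extract": {"element": [5, 9, 9], "largest_cc": False},
        "mesh": {"sigma_vox": 0.8, "iso": 0.5, "step_size": 2},
        "skeletonize": {"step_size": 5, "wave_count": 2},
        "trajectory": {"spacing_mm": 4.0, "vfov_deg": 60.0},
        "render": {"preset": "customlight", "resolution": 64, "max_frames": 6},
        "metrics": {"coverage_samples": 5000, "kid_subset": 8, "kid_subsets": 8},
    }


def _merge_validate(user: dict, defaults: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in (user or {}).items():
        if key not in defaults:
            raise PipelineError(f"unknown config key {path + key!r}")
        if isinstance(defaults[key], dict) and defaults[key]:
            out[key] = _merge_validate(val, defaults[key], path + key + ".")
        else:
            out[key] = val
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _save_png(img: np.ndarray, path: Path) -> None:
    Image.fromarray((np.clip(img, 0, 1) * 255).round().astype(np.uint8)).save(path)


def run_pipeline(config: dict | None = None, outdir: str | Path | None = None) -> dict:
    """Run the full pipeline; returns (and writes) the artifact manifest."""
    cfg = _merge_validate(config or {}, default_config())
    out = Path(outdir if outdir is not None else cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    (out / "frames").mkdir(exist_ok=True)
    cfg["outdir"] = str(out)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    seed = int(cfg["seed"])
    manifest: dict = {"config": cfg, "stages": []}

    def stage(name: str, params: dict, outputs: list[Path], compute) -> None:
        t0 = time.perf_counter()
        try:
            if not all(p.exists() for p in outputs):
                compute()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"[stage {name}] {exc}") from exc
        missing = [p for p in outputs if not p.exists()]
        if missing:
            raise PipelineError(f"[stage {name}] expected output missing: {missing[0]}")
        log.info("stage %-12s %6.2fs  params=%s", name, time.perf_counter() - t0, params)
        manifest["stages"].append({
            "name": name,
            "params": params,
            "outputs": [{"path": str(p.relative_to(out)), "sha256": _sha256(p)}
                        for p in outputs],
        })

    # -- phantom / inputs -------------------------------------------------
    ct_path = out / "ct.nii"
    kidney_path = out / "kidney.nii"
    truth_cl = out / "centerline.json"
    if cfg["inputs"]["ct"]:
        ct_path = Path(cfg["inputs"]["ct"])
        kidney_path = Path(cfg["inputs"]["kidney_mask"] or "")
        for p, role in [(ct_path, "ct"), (kidney_path, "kidney_mask")]:
            if not p.exists():
                raise PipelineError(f"[stage inputs] missing input file for {role}: {p}")
        manifest["stages"].append({"name": "inputs", "params": dict(cfg["inputs"]),
                                   "outputs": []})
    else:
        ph = cfg["phantom"]

        def make():
            spec = PhantomSpec(grid_shape=tuple(ph["grid_shape"]),
                               n_calyces=int(ph["n_calyces"]),
                               noise_sd=float(ph["noise_sd"]), rng_seed=seed)
            truth = make_phantom(spec)
            volumes.write_volume(truth.ct, ct_path)
            kidney = volumes.LabelMap((truth.labels.data > 0).astype(np.uint8),
                                      truth.labels.spacing, truth.labels.origin,
                                      {0: "background", 1: "kidney"})
            volumes.write_labelmap(kidney, kidney_path)
            volumes.write_labelmap(
                volumes.LabelMap((truth.labels.data == 2).astype(np.uint8),
                                 truth.labels.spacing, truth.labels.origin,
                                 {0: "background", 1: "collecting_system"}),
                out / "truth_cs.nii")
            truth_cl.write_text(json.dumps(
                [poly.tolist() for poly in truth.centerline]))

        stage("phantom", {**ph, "seed": seed},
              [ct_path, kidney_path, out / "truth_cs.nii", truth_cl], make)

    # -- preprocess -------------------------------------------------------
    norm_path = out / "ct_norm.nii"

    def preprocess():
        vol = volumes.read_volume(ct_path)
        if cfg["preprocess"]["resample_shape"]:
            vol = volumes.resample_to_shape(vol, tuple(cfg["preprocess"]["resample_shape"]))
        lo, hi = cfg["preprocess"]["clip"]
        volumes.write_volume(volumes.clip_normalize(vol, lo, hi), norm_path)

    stage("preprocess", dict(cfg["preprocess"]), [norm_path], preprocess)

    # -- extract ----------------------------------------------------------
    cs_path = out / "cs.nii"

    def extract():
        ct = volumes.read_volume(ct_path)
        kidney = volumes.read_labelmap(kidney_path)
        cs = extraction.extract_collecting_system(
            ct, kidney, tuple(cfg["extract"]["element"]),
            largest_cc=bool(cfg["extract"]["largest_cc"]))
        volumes.write_labelmap(cs, cs_path)

    stage("extract", dict(cfg["extract"]), [cs_path], extract)

    # -- mesh -------------------------------------------------------------
    mesh_path = out / "cs.ply"

    def mesh_stage():
        cs = volumes.read_labelmap(cs_path)
        field = meshing.smooth_binary(cs, float(cfg["mesh"]["sigma_vox"]))
        mesh = meshing.marching_cubes(field, float(cfg["mesh"]["iso"]),
                                      step_size=int(cfg["mesh"]["step_size"]))
        meshing.write_mesh(mesh, mesh_path)

    stage("mesh", dict(cfg["mesh"]), [mesh_path], mesh_stage)

    # -- skeletonize ------------------------------------------------------
    skel_path = out / "skeleton.json"

    def skeletonize():
        mesh = meshing.read_mesh(mesh_path)
        params = skel_mod.WaveParams(step_size=int(cfg["skeletonize"]["step_size"]),
                                     wave_count=int(cfg["skeletonize"]["wave_count"]),
                                     rng_seed=seed)
        skel_mod.skeletonize(mesh, params).to_json(skel_path)

    stage("skeletonize", {**cfg["skeletonize"], "seed": seed}, [skel_path], skeletonize)

    # -- trajectory -------------------------------------------------------
    poses_path = out / "poses.json"

    def trajectory():
        skel = skel_mod.Skeleton.from_json(skel_path)
        poses = sample_trajectory(skel, float(cfg["trajectory"]["spacing_mm"]),
                                            float(cfg["trajectory"]["vfov_deg"]))
        poses_path.write_text(json.dumps([p.to_dict() for p in poses]))

    stage("trajectory", dict(cfg["trajectory"]), [poses_path], trajectory)

    # -- render -----------------------------------------------------------
    n_frames_holder: dict = {}

    def frame_paths() -> list[Path]:
        poses = json.loads(poses_path.read_text())
        n = min(len(poses), int(cfg["render"]["max_frames"]))
        n_frames_holder["n"] = n
        return [out / "frames" / f"frame_{i:04d}.png" for i in range(n)]

    def render_stage():
        mesh = meshing.read_mesh(mesh_path)
        poses = json.loads(poses_path.read_text())
        n = n_frames_holder["n"]
        idx = np.linspace(0, len(poses) - 1, n).round().astype(int)
        preset = PRESETS[cfg["render"]["preset"]]
        res = int(cfg["render"]["resolution"])
        for i, j in enumerate(idx):
            p = poses[j]
            pose = CameraPose(np.asarray(p["position"]),
                                        np.asarray(p["view_dir"]),
                                        np.asarray(p["up"]), p["vfov_deg"])
            img = render_frame(mesh, pose, preset, (res, res))
            _save_png(img, out / "frames" / f"frame_{i:04d}.png")

    try:
        paths = frame_paths()
    except Exception as exc:
        raise PipelineError(f"[stage render] {exc}") from exc
    stage("render", dict(cfg["render"]), paths, render_stage)

    # -- metrics ----------------------------------------------------------
    metrics_path = out / "metrics.json"

    def metrics_stage():
        mesh = meshing.read_mesh(mesh_path)
        skel = skel_mod.Skeleton.from_json(skel_path)
        cov = skel_mod.coverage_distance(mesh, skel,
                                         int(cfg["metrics"]["coverage_samples"]),
                                         rng_seed=seed)
        frames = [np.asarray(Image.open(p), dtype=np.float64) / 255.0
                  for p in sorted((out / "frames").glob("frame_*.png"))]
        result = {"coverage_distance_mm": cov, "n_frames": len(frames)}
        if len(frames) >= 4:
            style = make_style_domain(frames, rng_seed=seed + 1)
            extractor = RandomProjectionExtractor(seed=0)
            fa, fb = extractor(frames), extractor(style)
            result["kid_rendered_vs_style"] = kid(
                fa, fb, subset_size=min(int(cfg["metrics"]["kid_subset"]), len(frames)),
                n_subsets=int(cfg["metrics"]["kid_subsets"]), rng_seed=seed)
        metrics_path.write_text(json.dumps(result, sort_keys=True))

    stage("metrics", {**cfg["metrics"], "seed": seed}, [metrics_path], metrics_stage)

    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
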