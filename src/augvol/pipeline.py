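"""End-to-end orchestration: register → crop → solidify → ROI Booleans →
fragment filtering → volume, with structured per-scan failure records.

The interactive steps of the original workflow (visual registration check,
hand-placed ROI, manual deletion of floating particles) are replaced by
numeric equivalents: an RMS quality gate after ICP, a scripted ROI box, and
connected-component filtering.  Any stage failure aborts that scan with a
structured error record; the remaining scans continue.

Re-measurement variability (two reading sessions t0/t1 of the same scans)
is emulated in :func:`run_study` by re-running with a jittered ROI
placement and a perturbed ICP initialisation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from . import mesh_io, roi_boolean, solidify, volume as volume_mod
from .errors import AugvolError, MarginError, RegistrationQualityError
from .registration import (
    ICPParams,
    RigidTransform,
    three_point_align,
    weighted_icp,
)


@dataclass
class PipelineConfig:
    """Everything a measurement run needs, YAML round-trippable."""

    solidify_depth: float = 6.0  # mm; must exceed registration residual scale
    solidify_mode: str = "plane"
    roi_scale: float = 0.98  # inner/outer ROI scale factor
    crop_pad: float = 3.0  # mm of wall kept around the outer ROI
    voxel_pitch: float = 0.1  # mm, Boolean subtraction grid
    fragment_policy: str = "largest"
    fragment_threshold: float = 0.05
    icp: ICPParams = field(default_factory=ICPParams)
    registration_gate: bool = True
    slice_oracle_thickness: float | None = None  # also run the slice method
    seed: int = 0

    def to_yaml(self, path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        icp = data.pop("icp", None)
        cfg = cls(**data)
        if icp:
            cfg.icp = ICPParams(**icp)
        return cfg


def measure_pair(
    baseline: trimesh.Trimesh,
    baseline_landmarks,
    augmented: trimesh.Trimesh,
    augmented_landmarks,
    roi_min,
    roi_max,
    weights: np.ndarray | None = None,
    config: PipelineConfig | None = None,
    roi_jitter: np.ndarray | None = None,
    init_perturbation: RigidTransform | None = None,
) -> dict:
    """Measure the volume added between one baseline/augmented scan pair.

    ``roi_min``/``roi_max`` define the outer ROI box in the baseline frame.
    ``roi_jitter`` (3-vector, mm) and ``init_perturbation`` emulate operator
    variability between reading sessions.  Returns a result dict with the
    measured volume, registration diagnostics and stage provenance.
    """
    cfg = config or PipelineConfig()
    roi_min = np.asarray(roi_min, float).copy()
    roi_max = np.asarray(roi_max, float).copy()
    if roi_jitter is not None:
        roi_min = roi_min + roi_jitter
        roi_max = roi_max + roi_jitter

    # 0. cheap margin pre-check on the baseline scan (needs no registration)
    crop_lo = roi_min[:2] - cfg.crop_pad
    crop_hi = roi_max[:2] + cfg.crop_pad
    b = baseline.bounds
    if (crop_lo < b[0][:2] - 1e-9).any() or (crop_hi > b[1][:2] + 1e-9).any():
        raise MarginError(
            f"ROI (+{cfg.crop_pad} mm wall) exceeds the baseline scan margin: "
            f"needs x/y {crop_lo}..{crop_hi}, scan has {b[0][:2]}..{b[1][:2]}"
        )

    # 1. coarse + refined registration (augmented -> baseline frame)
    coarse = three_point_align(augmented_landmarks, baseline_landmarks)
    init = coarse.transform
    if init_perturbation is not None:
        init = init_perturbation.compose(init)
    icp = weighted_icp(augmented, baseline, weights=weights, init=init, params=cfg.icp)
    if cfg.registration_gate and icp.final_rms > cfg.icp.quality_gate_rms:
        raise RegistrationQualityError(
            f"post-ICP weighted RMS {icp.final_rms:.3f} mm exceeds gate "
            f"{cfg.icp.quality_gate_rms} mm"
        )
    aligned = augmented.copy()
    aligned.vertices = icp.transform.apply(aligned.vertices)

    # 2. margin check on the aligned augmented scan
    b = aligned.bounds
    if (crop_lo < b[0][:2] - 1e-9).any() or (crop_hi > b[1][:2] + 1e-9).any():
        raise MarginError(
            f"ROI (+{cfg.crop_pad} mm wall) exceeds the augmented scan margin: "
            f"needs x/y {crop_lo}..{crop_hi}, scan has {b[0][:2]}..{b[1][:2]}"
        )

    # 3. crop to the ROI neighbourhood (open z)
    box = {
        "type": "box",
        "min": [crop_lo[0], crop_lo[1], -np.inf],
        "max": [crop_hi[0], crop_hi[1], np.inf],
    }
    base_patch = solidify.crop_mesh(baseline, box)
    aug_patch = solidify.crop_mesh(aligned, box)

    # 4. close both patches with the same closing direction so that the
    # added caps cancel exactly in the subtraction
    direction = solidify._closing_direction(base_patch)
    base_solid = solidify.close_to_solid(
        base_patch, depth=cfg.solidify_depth, direction=direction, mode=cfg.solidify_mode
    )
    aug_solid = solidify.close_to_solid(
        aug_patch, depth=cfg.solidify_depth, direction=direction, mode=cfg.solidify_mode
    )

    # 5. dual-ROI intersection
    roi = roi_boolean.box_roi(roi_min, roi_max, scale=cfg.roi_scale)
    base_roi = roi_boolean.boolean_intersect(base_solid, roi.outer)
    aug_roi = roi_boolean.boolean_intersect(aug_solid, roi.inner)

    # 6. subtraction + fragment filtering
    diff = roi_boolean.boolean_subtract(aug_roi, base_roi, pitch=cfg.voxel_pitch)
    n_components_raw = 0
    if len(diff.faces) == 0:
        result_volume = volume_mod.VolumeResult(
            volume_mm3=0.0, n_components=0, method="divergence", parameters={}
        )
        kept = diff
    else:
        n_components_raw = len(mesh_io.connected_components(diff))
        kept = roi_boolean.drop_disconnected(
            diff, policy=cfg.fragment_policy, threshold=cfg.fragment_threshold
        )
        result_volume = volume_mod.enclosed_volume(kept)

    out = {
        "status": "ok",
        "volume_cm3": result_volume.volume_cm3,
        "volume_mm3": result_volume.volume_mm3,
        "n_components_raw": n_components_raw,
        "n_components_kept": result_volume.n_components,
        "registration": {
            "coarse_residual_rms_mm": coarse.residual_rms,
            "icp_final_rms_mm": icp.final_rms,
            "icp_iterations": icp.n_iterations,
            "icp_converged": icp.converged,
            "transform": icp.transform.matrix.tolist(),
        },
        "roi": {"min": roi_min.tolist(), "max": roi_max.tolist(), "scale": cfg.roi_scale},
        "parameters": {
            "solidify_depth_mm": cfg.solidify_depth,
            "voxel_pitch_mm": cfg.voxel_pitch,
            "fragment_policy": cfg.fragment_policy,
        },
        "_meshes": {
            "diff": kept,
            "diff_raw": diff,
            "baseline_solid": base_solid,
            "augmented_solid": aug_solid,
        },
    }
    if cfg.slice_oracle_thickness and len(kept.faces):
        oracle = volume_mod.slice_volume_oracle(
            kept, slice_thickness=cfg.slice_oracle_thickness
        )
        out["slice_oracle_cm3"] = oracle.volume_cm3
    return out


def _strip_meshes(result: dict) -> dict:
    return {k: v for k, v in result.items() if not k.startswith("_")}


def run_pipeline(
    study_dir,
    config: PipelineConfig | None = None,
    out_dir=None,
    specimens=None,
    timepoint: str = "t0",
    jitter_sd_mm: float = 0.0,
    export_meshes: bool = False,
) -> list:
    """Run the measurement over a phantom-study directory layout.

    Expects the layout written by :func:`augvol.phantom.generate_study`
    (``manifest.csv`` + per-specimen STL/landmark/weight files).  Per-scan
    errors become structured failure records; other scans continue.
    """
    cfg = config or PipelineConfig()
    study = Path(study_dir)
    manifest_path = study / "manifest.csv"
    if not manifest_path.exists():
        from .errors import SchemaError

        raise SchemaError(f"no manifest.csv in {study}")
    manifest = pd.read_csv(manifest_path)
    if specimens is not None:
        manifest = manifest[manifest["specimen"].isin(specimens)]

    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 41, 0 if timepoint == "t0" else 1])
    )
    results = []
    for _, row in manifest.iterrows():
        sid, tech = row["specimen"], row["technique"]
        record = {"specimen": sid, "technique": tech, "timepoint": timepoint}
        try:
            base = mesh_io.read_stl(study / sid / "baseline.stl")
            lm_base = mesh_io.read_landmarks(study / sid / "baseline_landmarks.csv")
            aug = mesh_io.read_stl(study / sid / f"{tech}.stl")
            lm_aug = mesh_io.read_landmarks(study / sid / f"{tech}_landmarks.csv")
            wpath = study / sid / f"{tech}_weights.csv"
            weights = (
                mesh_io.read_weights(wpath, len(aug.vertices))
                if wpath.exists()
                else None
            )
            jitter = (
                rng.normal(0.0, jitter_sd_mm, 3) if jitter_sd_mm > 0 else None
            )
            perturb = None
            if jitter_sd_mm > 0:
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                ang = rng.normal(0.0, np.radians(0.5))
                K = np.array(
                    [
                        [0, -axis[2], axis[1]],
                        [axis[2], 0, -axis[0]],
                        [-axis[1], axis[0], 0],
                    ]
                )
                R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
                perturb = RigidTransform(R, rng.normal(0.0, 0.2, 3))
            res = measure_pair(
                base,
                lm_base,
                aug,
                lm_aug,
                roi_min=[row["roi_min_x"], row["roi_min_y"], row["roi_min_z"]],
                roi_max=[row["roi_max_x"], row["roi_max_y"], row["roi_max_z"]],
                weights=weights,
                config=cfg,
                roi_jitter=jitter,
                init_perturbation=perturb,
            )
            if export_meshes and out_dir is not None:
                mdir = Path(out_dir) / "meshes" / sid
                mdir.mkdir(parents=True, exist_ok=True)
                for name, mesh in res["_meshes"].items():
                    if len(mesh.faces):
                        mesh_io.write_stl(mesh, mdir / f"{tech}_{name}.stl")
            record.update(_strip_meshes(res))
            if "truth_cm3" in row:
                record["truth_cm3"] = float(row["truth_cm3"])
        except AugvolError as exc:
            record.update(
                {
                    "status": "failed",
                    "error_type": type(exc).__name__,
                    "error": str(exc),
                }
            )
        results.append(record)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / f"results_{timepoint}.json", "w") as fh:
            json.dump(results, fh, indent=2, sort_keys=True)
    return results


def results_to_frame(results: list) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "specimen": r.get("specimen"),
                "technique": r.get("technique"),
                "timepoint": r.get("timepoint"),
                "status": r.get("status"),
                "volume_cm3": r.get("volume_cm3", np.nan),
                "truth_cm3": r.get("truth_cm3", np.nan),
            }
        )
    return pd.DataFrame(rows)


def run_study(
    study_dir,
    config: PipelineConfig | None = None,
    out_dir=None,
    two_timepoints: bool = True,
    jitter_sd_mm: float = 0.3,
) -> pd.DataFrame:
    """Measure a whole study, optionally twice (t0 + jittered t1).

    Returns the tidy measurement table (one row per specimen × technique ×
    timepoint) consumed by the statistics layer; also writes it as CSV when
    ``out_dir`` is given.
    """
    cfg = config or PipelineConfig()
    res0 = run_pipeline(study_dir, cfg, out_dir=out_dir, timepoint="t0")
    frames = [results_to_frame(res0)]
    if two_timepoints:
        res1 = run_pipeline(
            study_dir, cfg, out_dir=out_dir, timepoint="t1", jitter_sd_mm=jitter_sd_mm
        )
        frames.append(results_to_frame(res1))
    table = pd.concat(frames, ignore_index=True)
    if out_dir is not None:
        table.to_csv(Path(out_dir) / "measurements.csv", index=False)
    return table
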