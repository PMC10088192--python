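"""End-to-end pipeline driver: simulate → fit maps → extract → infer.

Chains the phantom generator, the forward signal simulation, both
voxel-wise fitters, ROI extraction and the GEE analysis into one
deterministic run. Every artifact written is listed in a manifest with
a content hash; stage logs record the acquisition constants in effect
and per-map voxel counts for auditability.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import inference
from .config import StudyConfig
from .diffusion import fit_dti_maps
from .phantom import CONDITIONS, PARAMETERS, REGIONS, default_study_spec
from .protocol import AcquisitionProtocol, Geometry
from .relaxometry import fit_t1_map
from .rois import ROISet, extract_observations, summarize
from .signals import sigma_for_snr, simulate_animal
from .volume import ImageVolume, write_volume


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: StudyConfig) -> dict:
    """Run a full synthetic study; returns the run manifest.

    Deterministic for a fixed config seed: rerunning writes
    byte-identical artifacts.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    geometry = Geometry(
        matrix=config.matrix,
        n_slices=config.n_slices,
        in_plane_resolution_mm=config.in_plane_resolution_mm,
        slice_thickness_mm=config.slice_thickness_mm,
    )
    spec = default_study_spec(geometry=geometry, animals_per_group=config.group_sizes())
    protocol = AcquisitionProtocol(geometry=geometry)
    sigma = sigma_for_snr(spec.s0, config.snr)
    rois = ROISet.from_phantom(spec)

    manifest: dict = {
        "seed": config.seed,
        "constants": {
            "tr_list_ms": list(protocol.tr_list_ms),
            "b_values": list(protocol.b_values),
            "n_directions": int(protocol.directions.shape[0]),
            "r2_threshold": config.r2_threshold,
            "snr": config.snr,
            "significance_level": inference.SIGNIFICANCE_LEVEL,
        },
        "stages": {},
        "artifacts": {},
    }

    def record(path: Path) -> None:
        manifest["artifacts"][str(path.relative_to(out))] = _sha256(path)

    stage = "simulate"
    try:
        from .phantom import make_study, study_design_table

        animals = make_study(spec, config.seed)
        design = study_design_table(animals)
        design_path = out / "study_design.csv"
        design.to_csv(design_path, index=False)
        record(design_path)

        label_path = out / "roi_labels.nii"
        written = write_volume(ImageVolume(rois.labels.astype(float), geometry.voxel_size_mm), label_path)
        for p in written:
            record(p)

        noise_root = np.random.SeedSequence(config.seed).spawn(1)[0].spawn(len(animals))

        stage = "fit"
        tables, extraction_logs = [], []
        fit_counts = {}
        for animal, noise_seed in zip(animals, noise_root):
            t1_series, dwi_series = simulate_animal(animal, protocol, sigma, noise_seed)
            if config.write_nifti:
                for vol, suffix in ((t1_series, "t1series"), (dwi_series, "dwi")):
                    for p in write_volume(vol, out / f"{animal.animal_id}_{suffix}.nii"):
                        record(p)
            t1_map = fit_t1_map(t1_series, protocol, config.r2_threshold)
            md_map, fa_map = fit_dti_maps(dwi_series, protocol, config.r2_threshold)
            fit_counts[animal.animal_id] = {
                m.name: {"valid": m.n_valid, "masked": int(m.values.size - m.n_valid)}
                for m in (t1_map, md_map, fa_map)
            }
            if config.write_nifti:
                for m in (t1_map, md_map, fa_map):
                    for arr, tag in ((m.values, m.name.lower()), (m.r_squared, f"{m.name.lower()}_r2")):
                        for p in write_volume(
                            ImageVolume(np.nan_to_num(arr, nan=0.0, neginf=0.0), geometry.voxel_size_mm),
                            out / f"{animal.animal_id}_{tag}.nii",
                        ):
                            record(p)
            stage = "extract"
            table, log = extract_observations(
                {"T1": t1_map, "MD": md_map, "FA": fa_map},
                rois,
                animal.animal_id,
                animal.state,
                animal.condition,
                tumor_side=spec.tumor_side,
            )
            tables.append(table)
            extraction_logs.append(log)
            stage = "fit"

        stage = "extract"
        observations = pd.concat(tables, ignore_index=True)
        obs_path = out / "observations.csv"
        observations.to_csv(obs_path, index=False)
        record(obs_path)
        manifest["stages"]["fit"] = fit_counts
        manifest["stages"]["extract"] = extraction_logs

        stage = "infer"
        if observations.empty:
            warnings.warn("observation table is empty; inference skipped", stacklevel=2)
            results = pd.DataFrame()
        else:
            summary_path = out / "summary.csv"
            summarize(observations).to_csv(summary_path, index=False)
            record(summary_path)
            results = _inference_results(observations, config.working_correlation)
        results_path = out / "results.csv"
        results.to_csv(results_path, index=False)
        record(results_path)
    except Exception as exc:
        manifest["failed_stage"] = stage
        _write_manifest(out, manifest)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _write_manifest(out, manifest)
    return manifest


def _inference_results(observations: pd.DataFrame, working_correlation: str) -> pd.DataFrame:
    """Per-parameter GEE effect tests and all pairwise cell contrasts."""
    rows = []
    for parameter in PARAMETERS:
        sub = observations.loc[observations["parameter"] == parameter]
        if sub.empty:
            continue
        result = inference.fit_gee(sub, working_correlation=working_correlation)
        for _, w in result.wald_tests.iterrows():
            rows.append(
                {
                    "parameter": parameter,
                    "kind": "wald",
                    "term": w["effect"],
                    "estimate": np.nan,
                    "robust_se": np.nan,
                    "statistic": w["statistic"],
                    "df": w["df"],
                    "p": w["p"],
                }
            )
        for region in REGIONS:
            for condition in CONDITIONS:
                c = inference.pairwise_contrast(
                    result, "state", "control", "tumor", condition=condition, region=region
                )
                rows.append(
                    {
                        "parameter": parameter,
                        "kind": "contrast",
                        "term": c.description,
                        "estimate": c.estimate,
                        "robust_se": c.se,
                        "statistic": c.z,
                        "df": 1,
                        "p": c.p,
                    }
                )
            for state in ("control", "tumor"):
                c = inference.pairwise_contrast(
                    result, "condition", "fed", "fasted", state=state, region=region
                )
                rows.append(
                    {
                        "parameter": parameter,
                        "kind": "contrast",
                        "term": c.description,
                        "estimate": c.estimate,
                        "robust_se": c.se,
                        "statistic": c.z,
                        "df": 1,
                        "p": c.p,
                    }
                )
    return pd.DataFrame(rows)


def _write_manifest(out: Path, manifest: dict) -> Path:
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
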